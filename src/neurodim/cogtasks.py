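"""Rate-RNN simulator and cognitive-task battery.

A continuous-rate recurrent network with softplus units,

    tau dr/dt = -r + f(W_rec r + W_in u + b + sqrt(2 tau sigma_rec^2) xi),

Euler-discretized as

    r_t = (1 - alpha) r_{t-1} + alpha f(W_rec r_{t-1} + W_in u_t + b + noise),

with alpha = dt/tau and logistic readout z = sigmoid(W_out r), is trained on
a battery of 20 interrelated cognitive tasks (Go, Decision-Making and
Matching families) with ring-coded angular stimuli and responses.  The
input layer is one fixation unit plus two 32-unit stimulus rings; the
output layer is one fixation unit plus a 32-unit response ring.  Ring unit
``i`` has preferred direction ``psi_i = pi/16 * i`` and responds to a
stimulus at angle ``psi`` with

    u_i = gamma * 0.8 * exp(-0.5 * (8 |psi - psi_i| / pi)^2),

the angular difference taken on the circle (wrapped to [0, pi]); multiple
stimuli sum.  The set of recurrent-layer configurations visited across
trials of a trained network is the neural manifold whose intrinsic
dimension the rest of the package measures.

Training uses masked squared-error loss on the outputs, backpropagation
through time, and Adam, all implemented on numpy arrays.  Epoch durations,
network size, and noise levels live in :class:`SimConfig` so the same code
runs both the full 256-unit configuration and scaled-down test networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GO_FAMILY",
    "MATCHING_FAMILY",
    "DM_FAMILY",
    "RNNParams",
    "SimConfig",
    "TASKS",
    "TaskTrial",
    "TrainResult",
    "accuracy",
    "collect_manifold",
    "decode_response",
    "init_params",
    "make_trial",
    "simulate",
    "train",
    "tuning_curve",
]

N_RING = 32

GO_FAMILY = ("fd_go", "rt_go", "dly_go", "fd_anti", "rt_anti", "dly_anti")
DM_FAMILY = (
    "dm1", "dm2", "ctx_dm1", "ctx_dm2", "multi_dm",
    "dly_dm1", "dly_dm2", "ctx_dly_dm1", "ctx_dly_dm2", "multi_dly_dm",
)
MATCHING_FAMILY = ("dms", "dnms", "dmc", "dnmc")
TASKS = GO_FAMILY + DM_FAMILY + MATCHING_FAMILY


@dataclass(frozen=True)
class SimConfig:
    """Network architecture, integration and trial-timing parameters.

    Defaults follow the standard battery configuration: 256 recurrent
    units, tau = 100 ms with dt = 20 ms (alpha = 0.2), recurrent noise
    sigma_rec = 0.05 and input noise sigma_in = 0.01.  Epoch durations are
    a configurable choice (the battery's timing is not fixed by a single
    convention); response decoding tolerance is +-36 degrees.
    """

    n_rec: int = 256
    tau_ms: float = 100.0
    dt_ms: float = 20.0
    sigma_rec: float = 0.05
    sigma_in: float = 0.01
    fix_ms: float = 300.0
    stim_ms: float = 500.0
    delay_ms: float = 500.0
    resp_ms: float = 400.0
    grace_ms: float = 100.0
    resp_tolerance_rad: float = np.pi / 5.0

    n_in: int = field(init=False, default=2 * N_RING + 1)
    n_out: int = field(init=False, default=N_RING + 1)

    @property
    def alpha(self) -> float:
        a = self.dt_ms / self.tau_ms
        if not 0 < a <= 1:
            raise ValueError("dt/tau must lie in (0, 1]")
        return a

    def steps(self, ms: float) -> int:
        return max(1, int(round(ms / self.dt_ms)))


@dataclass
class RNNParams:
    """Unconstrained input, recurrent and output weights plus bias."""

    W_in: np.ndarray
    W_rec: np.ndarray
    W_out: np.ndarray
    b: np.ndarray


@dataclass(frozen=True)
class TaskTrial:
    """Inputs, targets and loss mask for a single trial.

    ``inputs`` is T x n_in (fixation unit, then two stimulus rings),
    ``targets`` and ``loss_mask`` are T x n_out (fixation output, then the
    response ring).  ``meta`` records the task name, stimulus angles and
    intensities, the target response angle (None for withheld responses)
    and epoch boundaries in steps.
    """

    inputs: np.ndarray
    targets: np.ndarray
    loss_mask: np.ndarray
    meta: dict


def _wrap_angle_diff(a: np.ndarray | float) -> np.ndarray | float:
    """Minimal angular distance, in [0, pi]."""
    d = np.abs(np.mod(a, 2 * np.pi))
    return np.minimum(d, 2 * np.pi - d)


def tuning_curve(psi: float, gamma: float, n_units: int = N_RING) -> np.ndarray:
    """Ring-population response to a stimulus at angle psi with strength gamma."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    psi_i = 2 * np.pi * np.arange(n_units) / n_units
    d = _wrap_angle_diff(psi - psi_i)
    return gamma * 0.8 * np.exp(-0.5 * (8.0 * d / np.pi) ** 2)


def _ring_target(psi: float | None, n_units: int = N_RING) -> np.ndarray:
    """Response-ring target bump (baseline 0.05, peak 0.85)."""
    base = np.full(n_units, 0.05)
    if psi is None:
        return base
    return base + tuning_curve(psi, 1.0, n_units)


class _TrialBuilder:
    """Assembles input/target/mask arrays from epoch segments."""

    def __init__(self, cfg: SimConfig, t_total: int):
        self.cfg = cfg
        self.T = t_total
        self.u = np.zeros((t_total, cfg.n_in))
        self.y = np.zeros((t_total, cfg.n_out))
        self.mask = np.ones((t_total, cfg.n_out))
        # default: fixate (and no response) everywhere
        self.u[:, 0] = 1.0
        self.y[:, 0] = 0.8
        self.y[:, 1:] = 0.05

    def stimulus(self, t0: int, t1: int, psi: float, gamma: float, modality: int):
        lo = 1 + (modality - 1) * N_RING
        self.u[t0:t1, lo : lo + N_RING] += tuning_curve(psi, gamma)

    def go(self, t_go: int, psi_resp: float | None):
        """Fixation cue off and response target from t_go to trial end."""
        cfg = self.cfg
        self.u[t_go:, 0] = 0.0
        self.y[t_go:, 0] = 0.05
        self.y[t_go:, 1:] = _ring_target(psi_resp)
        g = cfg.steps(cfg.grace_ms)
        self.mask[t_go : t_go + g, :] = 0.0
        self.mask[t_go + g :, :] = 5.0

    def withhold(self, t_go: int):
        """Fixation cue off but the correct response is to keep fixating."""
        cfg = self.cfg
        self.u[t_go:, 0] = 0.0
        g = cfg.steps(cfg.grace_ms)
        self.mask[t_go + g :, :] = 5.0

    def finish(self, meta: dict) -> TaskTrial:
        return TaskTrial(inputs=self.u, targets=self.y, loss_mask=self.mask, meta=meta)


def make_trial(task: str, seed: int, cfg: SimConfig | None = None) -> TaskTrial:
    """Generate one noiseless-input trial of the given task.

    Input noise (sqrt(2/alpha) * sigma_in per step) is added at simulation
    time, not here, so a trial can be replayed under different noise seeds.
    """
    if cfg is None:
        cfg = SimConfig()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; known tasks: {', '.join(TASKS)}")
    rng = np.random.default_rng(seed)
    fix, stim, delay, resp = (
        cfg.steps(cfg.fix_ms), cfg.steps(cfg.stim_ms),
        cfg.steps(cfg.delay_ms), cfg.steps(cfg.resp_ms),
    )
    psi1 = float(rng.uniform(0, 2 * np.pi))
    meta: dict = {"task": task, "seed": seed}

    if task in GO_FAMILY:
        anti = task.endswith("anti")
        modality = int(rng.integers(1, 3))
        psi_resp = (psi1 + np.pi) % (2 * np.pi) if anti else psi1
        if task.startswith("fd"):
            T = fix + stim + resp
            tb = _TrialBuilder(cfg, T)
            tb.stimulus(fix, T, psi1, 1.0, modality)
            tb.go(fix + stim, psi_resp)
            epochs = {"stim_on": fix, "go": fix + stim}
        elif task.startswith("rt"):
            T = fix + stim + resp
            tb = _TrialBuilder(cfg, T)
            tb.stimulus(fix, T, psi1, 1.0, modality)
            tb.go(fix, psi_resp)  # respond as soon as the stimulus appears
            epochs = {"stim_on": fix, "go": fix}
        else:  # dly
            T = fix + stim + delay + resp
            tb = _TrialBuilder(cfg, T)
            tb.stimulus(fix, fix + stim, psi1, 1.0, modality)
            tb.go(fix + stim + delay, psi_resp)
            epochs = {"stim_on": fix, "stim_off": fix + stim, "go": fix + stim + delay}
        meta.update(psi=psi1, psi_resp=psi_resp, modality=modality, epochs=epochs)
        return tb.finish(meta)

    if task in DM_FAMILY:
        # second stimulus 90..270 degrees away from the first
        psi2 = (psi1 + rng.uniform(np.pi / 2, 3 * np.pi / 2)) % (2 * np.pi)
        c = float(rng.choice([0.08, 0.16, 0.32]))
        sign = 1 if rng.random() < 0.5 else -1
        g1, g2 = 1.0 + sign * c / 2, 1.0 - sign * c / 2
        delayed = "dly" in task
        if task in ("multi_dm", "multi_dly_dm"):
            # strengths split across modalities; respond to the larger sum
            w1, w2 = rng.uniform(0.4, 0.6, size=2)
            stim_spec = [
                (psi1, g1 * w1, 1), (psi2, g2 * w2, 1),
                (psi1, g1 * (1 - w1), 2), (psi2, g2 * (1 - w2), 2),
            ]
            psi_resp = psi1 if g1 >= g2 else psi2
        elif task.startswith("ctx"):
            attended = 1 if task in ("ctx_dm1", "ctx_dly_dm1") else 2
            other = 3 - attended
            psi1o = float(rng.uniform(0, 2 * np.pi))
            psi2o = (psi1o + rng.uniform(np.pi / 2, 3 * np.pi / 2)) % (2 * np.pi)
            co = float(rng.choice([0.08, 0.16, 0.32]))
            so = 1 if rng.random() < 0.5 else -1
            stim_spec = [
                (psi1, g1, attended), (psi2, g2, attended),
                (psi1o, 1 + so * co / 2, other), (psi2o, 1 - so * co / 2, other),
            ]
            psi_resp = psi1 if g1 >= g2 else psi2
        else:
            modality = 1 if task in ("dm1", "dly_dm1") else 2
            stim_spec = [(psi1, g1, modality), (psi2, g2, modality)]
            psi_resp = psi1 if g1 >= g2 else psi2
        if delayed:
            T = fix + stim + delay + stim + delay // 2 + resp
            tb = _TrialBuilder(cfg, T)
            for k, (psi, g, mod) in enumerate(stim_spec):
                first = k % 2 == 0
                t0 = fix if first else fix + stim + delay
                tb.stimulus(t0, t0 + stim, psi, g, mod)
            t_go = fix + stim + delay + stim + delay // 2
        else:
            T = fix + stim + resp
            tb = _TrialBuilder(cfg, T)
            for psi, g, mod in stim_spec:
                tb.stimulus(fix, T, psi, g, mod)
            t_go = fix + stim
        tb.go(t_go, psi_resp)
        meta.update(psi=psi1, psi2=psi2, psi_resp=psi_resp,
                    gammas=(g1, g2), epochs={"go": t_go})
        return tb.finish(meta)

    # matching family: two successive stimuli separated by a delay
    match_trial = bool(rng.random() < 0.5)
    categorical = task in ("dmc", "dnmc")
    if categorical:
        if match_trial:
            # same category (category 0: [0, pi), category 1: [pi, 2 pi))
            cat = int(psi1 >= np.pi)
            psi2 = float(rng.uniform(cat * np.pi, (cat + 1) * np.pi))
        else:
            cat = int(psi1 >= np.pi)
            psi2 = float(rng.uniform((1 - cat) * np.pi, (2 - cat) * np.pi))
    else:
        psi2 = psi1 if match_trial else float(
            (psi1 + rng.uniform(np.pi / 4, 7 * np.pi / 4)) % (2 * np.pi)
        )
    respond = match_trial if task in ("dms", "dmc") else not match_trial
    modality = int(rng.integers(1, 3))
    T = fix + stim + delay + stim + resp
    tb = _TrialBuilder(cfg, T)
    tb.stimulus(fix, fix + stim, psi1, 1.0, modality)
    t2 = fix + stim + delay
    tb.stimulus(t2, t2 + stim, psi2, 1.0, modality)
    t_go = t2 + stim
    if respond:
        tb.go(t_go, psi2)
        psi_resp: float | None = psi2
    else:
        tb.withhold(t_go)
        psi_resp = None
    meta.update(psi=psi1, psi2=psi2, match=match_trial, psi_resp=psi_resp,
                modality=modality, epochs={"stim2_on": t2, "go": t_go})
    return tb.finish(meta)


# ---------------------------------------------------------------------------
# simulation


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.exp(-np.abs(x), out=out)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    out[~pos] = out[~pos] / (1.0 + out[~pos])
    return out


def init_params(cfg: SimConfig, seed: int) -> RNNParams:
    """Gaussian initialization, recurrent weights scaled to spectral radius ~0.5."""
    rng = np.random.default_rng(seed)
    n = cfg.n_rec
    w_rec = rng.normal(scale=0.5 / np.sqrt(n), size=(n, n))
    return RNNParams(
        W_in=rng.normal(scale=1.0 / np.sqrt(cfg.n_in), size=(n, cfg.n_in)),
        W_rec=w_rec,
        W_out=rng.normal(scale=1.0 / np.sqrt(n), size=(cfg.n_out, n)),
        b=np.zeros(n),
    )


def _forward(
    params: RNNParams,
    inputs: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler recursion over a batch.  inputs: (B, T, n_in).

    Returns (r, h, z): rates (B, T, n_rec), pre-activations (B, T, n_rec)
    and outputs (B, T, n_out).  ``rng=None`` disables both recurrent and
    input noise (deterministic run).  r_0 = 0.
    """
    B, T, _ = inputs.shape
    a = cfg.alpha
    n = cfg.n_rec
    u = inputs
    if rng is not None and cfg.sigma_in > 0:
        u = u + np.sqrt(2.0 / a) * cfg.sigma_in * rng.standard_normal(u.shape)
    r = np.zeros((B, T, n))
    h = np.zeros((B, T, n))
    state = np.zeros((B, n))
    noise_scale = np.sqrt(2.0 / a) * cfg.sigma_rec
    u_proj = u @ params.W_in.T + params.b
    for t in range(T):
        ht = state @ params.W_rec.T + u_proj[:, t]
        if rng is not None and cfg.sigma_rec > 0:
            ht = ht + noise_scale * rng.standard_normal(ht.shape)
        h[:, t] = ht
        state = (1.0 - a) * state + a * _softplus(ht)
        r[:, t] = state
    z = _sigmoid(r @ params.W_out.T)
    if not np.all(np.isfinite(r)):
        bad = int(np.argwhere(~np.isfinite(r).all(axis=(0, 2)))[0, 0])
        raise FloatingPointError(f"non-finite network state at step {bad}")
    return r, h, z


def simulate(
    params: RNNParams,
    trial: TaskTrial,
    seed: int = 0,
    noise_on: bool = True,
    cfg: SimConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one trial; returns (activity T x n_rec, outputs T x n_out)."""
    if cfg is None:
        cfg = SimConfig(n_rec=params.W_rec.shape[0])
    rng = np.random.default_rng(seed) if noise_on else None
    r, _, z = _forward(params, trial.inputs[None], cfg, rng)
    return r[0], z[0]


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainResult:
    params: RNNParams
    accuracy: float
    converged: bool
    n_steps: int
    loss_history: list[float] = field(repr=False, default_factory=list)


def _loss_and_grads(
    params: RNNParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[float, dict[str, np.ndarray]]:
    """Masked MSE loss and exact BPTT gradients for one minibatch."""
    a = cfg.alpha
    r, h, z = _forward(params, inputs, cfg, rng)
    norm = mask.sum() + 1e-12
    err = (z - targets) * mask
    loss = float((err * (z - targets)).sum() / norm)
    dz = 2.0 * err * z * (1.0 - z) / norm          # (B, T, n_out)
    gW_out = np.einsum("bto,btn->on", dz, r)
    dr_out = dz @ params.W_out                      # (B, T, n_rec)
    B, T, n = r.shape
    fprime = _sigmoid(h)                            # softplus' = sigmoid
    gW_rec = np.zeros_like(params.W_rec)
    gW_in = np.zeros_like(params.W_in)
    gb = np.zeros_like(params.b)
    g = np.zeros((B, n))
    u = inputs
    for t in range(T - 1, -1, -1):
        g = g + dr_out[:, t]
        e = g * (a * fprime[:, t])                  # (B, n)
        r_prev = r[:, t - 1] if t > 0 else np.zeros((B, n))
        gW_rec += e.T @ r_prev
        gW_in += e.T @ u[:, t]
        gb += e.sum(axis=0)
        g = (1.0 - a) * g + e @ params.W_rec
    return loss, {"W_in": gW_in, "W_rec": gW_rec, "W_out": gW_out, "b": gb}


def decode_response(
    outputs: np.ndarray, trial: TaskTrial, cfg: SimConfig
) -> float | None:
    """Population-vector readout of the response ring after the go cue.

    Averages ring outputs over the post-grace response epoch; returns the
    population-vector angle, or None if the ring stays below threshold
    (a withheld response).
    """
    t_go = trial.meta["epochs"]["go"]
    g = cfg.steps(cfg.grace_ms)
    ring = outputs[t_go + g :, 1:].mean(axis=0)
    if ring.max() < 0.3:
        return None
    psi_i = 2 * np.pi * np.arange(ring.size) / ring.size
    vec = np.sum(ring * np.exp(1j * psi_i))
    return float(np.angle(vec) % (2 * np.pi))


def _trial_correct(outputs: np.ndarray, trial: TaskTrial, cfg: SimConfig) -> bool:
    resp = decode_response(outputs, trial, cfg)
    target = trial.meta.get("psi_resp")
    if target is None:
        return resp is None
    if resp is None:
        return False
    return bool(_wrap_angle_diff(resp - target) <= cfg.resp_tolerance_rad)


def accuracy(
    params: RNNParams,
    task: str,
    n_trials: int = 100,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> float:
    """Fraction of held-out trials with a correct decoded response.

    Correct: decoded population-vector angle within the configured tolerance
    of the target during the response epoch (or a properly withheld
    response on no-go trials).
    """
    if cfg is None:
        cfg = SimConfig(n_rec=params.W_rec.shape[0])
    rng = np.random.default_rng(seed)
    n_ok = 0
    for k in range(n_trials):
        trial = make_trial(task, int(rng.integers(2**31)), cfg)
        _, z = simulate(params, trial, seed=int(rng.integers(2**31)),
                        noise_on=True, cfg=cfg)
        n_ok += _trial_correct(z, trial, cfg)
    return n_ok / n_trials


def train(
    task: str,
    seed: int = 0,
    budget: int = 1500,
    cfg: SimConfig | None = None,
    batch_size: int = 32,
    lr: float = 3e-3,
    target_accuracy: float = 0.95,
    eval_every: int = 50,
) -> TrainResult:
    """Train a network on one task with Adam; early-stops at target accuracy.

    Returns best-so-far parameters with ``converged=False`` if the accuracy
    target is not reached within the budget (some matching-family tasks are
    genuinely hard to train), never raising.
    """
    if cfg is None:
        cfg = SimConfig()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    params = init_params(cfg, seed)
    m = {k: np.zeros_like(getattr(params, k)) for k in ("W_in", "W_rec", "W_out", "b")}
    v = {k: np.zeros_like(getattr(params, k)) for k in ("W_in", "W_rec", "W_out", "b")}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    history: list[float] = []
    best_acc, best_params = -1.0, params
    converged = False
    steps_done = 0
    for step in range(1, budget + 1):
        trials = [make_trial(task, int(rng.integers(2**31)), cfg)
                  for _ in range(batch_size)]
        T = max(t.inputs.shape[0] for t in trials)
        u = np.zeros((batch_size, T, cfg.n_in))
        y = np.zeros((batch_size, T, cfg.n_out))
        msk = np.zeros((batch_size, T, cfg.n_out))
        for i, t in enumerate(trials):
            L = t.inputs.shape[0]
            u[i, :L], y[i, :L], msk[i, :L] = t.inputs, t.targets, t.loss_mask
        loss, grads = _loss_and_grads(params, u, y, msk, cfg, rng)
        history.append(loss)
        for k, gk in grads.items():
            m[k] = beta1 * m[k] + (1 - beta1) * gk
            v[k] = beta2 * v[k] + (1 - beta2) * gk**2
            mhat = m[k] / (1 - beta1**step)
            vhat = v[k] / (1 - beta2**step)
            setattr(params, k, getattr(params, k) - lr * mhat / (np.sqrt(vhat) + eps))
        steps_done = step
        if step % eval_every == 0 or step == budget:
            acc = accuracy(params, task, n_trials=50,
                           seed=int(rng.integers(2**31)), cfg=cfg)
            if acc > best_acc:
                best_acc = acc
                best_params = RNNParams(**{k: getattr(params, k).copy()
                                           for k in ("W_in", "W_rec", "W_out", "b")})
            if acc >= target_accuracy:
                converged = True
                break
    return TrainResult(params=best_params, accuracy=best_acc,
                       converged=converged, n_steps=steps_done,
                       loss_history=history)


def collect_manifold(
    params: RNNParams,
    task: str,
    n_trials: int = 200,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> np.ndarray:
    """Recurrent-layer activity across trials, one row per time step.

    The concatenated (n_trials * T) x n_rec array is the neural manifold:
    the set of population-activity configurations visited by the network
    while performing the task.
    """
    if cfg is None:
        cfg = SimConfig(n_rec=params.W_rec.shape[0])
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_trials):
        trial = make_trial(task, int(rng.integers(2**31)), cfg)
        r, _ = simulate(params, trial, seed=int(rng.integers(2**31)),
                        noise_on=True, cfg=cfg)
        rows.append(r)
    return np.concatenate(rows, axis=0)
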