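"""Seeded generators for synthetic benchmark manifolds and neural trajectories.

Every generator is bit-reproducible for a fixed seed and parameter set and
records its true intrinsic dimension, so estimator accuracy can be scored
exactly.  The latent-trajectory generator emulates multi-electrode-style
recordings: d independent latent rate channels, temporally smoothed, mixed
linearly into N ambient channels, optionally passed through a saturating
exponential nonlinearity.  Both embedding steps preserve the intrinsic
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "EmbeddingSpec",
    "ManifoldSample",
    "anisotropic_flat",
    "latent_trajectories",
    "linear_embed",
    "nonlinear_embed",
    "repeated_stimulus_responses",
    "swiss_roll",
    "uniform_hypercube",
    "uniform_hyperplane",
    "uniform_hypersphere",
]

DEFAULT_AMBIENT = 96  # ~ number of electrodes in a multi-electrode array


@dataclass(frozen=True)
class ManifoldSample:
    """A generated point cloud with its ground-truth intrinsic dimension."""

    points: np.ndarray
    true_id: int
    generator_name: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Parameters of the latent-to-ambient embedding."""

    mixing_matrix: np.ndarray
    nonlinearity_alpha: float = 0.0
    smoothing_sd_ms: float = 50.0
    bin_ms: float = 50.0


def _rotation(d: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal d x n map into the ambient space (random rotation)."""
    q, r = np.linalg.qr(rng.normal(size=(n, d)))
    return (q * np.sign(np.diag(r))).T


def uniform_hyperplane(
    d: int, n_ambient: int, p: int, seed: int
) -> ManifoldSample:
    """p points uniform on a bounded d-dim patch, rotated into n_ambient dims."""
    if d > n_ambient:
        raise ValueError("d must be <= n_ambient")
    rng = np.random.default_rng(seed)
    rot = _rotation(d, n_ambient, rng)
    latent = rng.uniform(-1.0, 1.0, size=(p, d))
    return ManifoldSample(
        points=latent @ rot, true_id=d, generator_name="uniform_hyperplane",
        params={"d": d, "n_ambient": n_ambient, "p": p, "seed": seed},
    )


def swiss_roll(p: int, seed: int, noise_sd: float = 0.0) -> ManifoldSample:
    """Area-uniform sample of the Swiss roll (t cos t, y, t sin t).

    t in [1.5 pi, 4.5 pi], y in [0, 20]; the surface element is
    sqrt(1 + t^2) dt dy, sampled exactly by inverse-CDF interpolation on a
    fine t grid.  Optional isotropic Gaussian ambient noise.
    """
    if p < 100:
        raise ValueError("p must be >= 100")
    rng = np.random.default_rng(seed)
    t0, t1 = 1.5 * np.pi, 4.5 * np.pi
    grid = np.linspace(t0, t1, 4096)
    density = np.sqrt(1.0 + grid**2)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    t = np.interp(rng.uniform(size=p), cdf, grid)
    y = rng.uniform(0.0, 20.0, size=p)
    pts = np.column_stack([t * np.cos(t), y, t * np.sin(t)])
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return ManifoldSample(
        points=pts, true_id=2, generator_name="swiss_roll",
        params={"p": p, "seed": seed, "noise_sd": noise_sd},
    )


def uniform_hypercube(d: int, p: int, seed: int) -> ManifoldSample:
    """p iid uniform points in the unit cube [0, 1]^d."""
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    return ManifoldSample(
        points=rng.uniform(size=(p, d)), true_id=d,
        generator_name="uniform_hypercube", params={"d": d, "p": p, "seed": seed},
    )


def uniform_hypersphere(d_sphere: int, p: int, seed: int) -> ManifoldSample:
    """p uniform points on the unit sphere S^{d_sphere} in d_sphere+1 dims."""
    if d_sphere < 1:
        raise ValueError("d_sphere must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(p, d_sphere + 1))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    return ManifoldSample(
        points=x, true_id=d_sphere, generator_name="uniform_hypersphere",
        params={"d_sphere": d_sphere, "p": p, "seed": seed},
    )


def anisotropic_flat(
    d: int, p: int, alpha_aniso: float, seed: int
) -> ManifoldSample:
    """Flat d-dim data with a tunable density gradient.

    Starts from iid uniform in [-1, 1]^d and maps each coordinate
    x -> sign(x) |x|^(1 + alpha_aniso): alpha_aniso = 0 is isotropic, larger
    values concentrate mass near the origin and the coordinate axes while
    the support stays flat (the delta curvature statistic should remain
    below 2 at any anisotropy).
    """
    if alpha_aniso < 0:
        raise ValueError("alpha_aniso must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-1.0, 1.0, size=(p, d))
    pts = np.sign(x) * np.abs(x) ** (1.0 + alpha_aniso)
    return ManifoldSample(
        points=pts, true_id=d, generator_name="anisotropic_flat",
        params={"d": d, "p": p, "alpha_aniso": alpha_aniso, "seed": seed},
    )


def _gaussian_smooth(x: np.ndarray, sd_bins: float) -> np.ndarray:
    """Gaussian temporal smoothing along axis 0, reflect-padded."""
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(x, sigma=sd_bins, axis=0, mode="reflect")


def latent_trajectories(
    d: int,
    p: int,
    seed: int,
    rate_model: str = "lognormal",
    smoothing_sd_ms: float = 50.0,
    bin_ms: float = 50.0,
    smooth: bool = True,
) -> np.ndarray:
    """d-dimensional latent rate trajectories (p time bins).

    Samples are drawn iid per bin from the configured rate distribution and
    then temporally smoothed with a Gaussian kernel (s.d. 50 ms at a 50 ms
    binning by default, i.e. one bin).

    ``rate_model``:
      - ``"lognormal"``: log-normal rates with unit log-scale — a synthetic
        stand-in for heavy-tailed empirical cortical firing-rate samples;
      - ``"equal_variance"``: standard Gaussian latents, giving every latent
        channel the same variance.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    if rate_model == "lognormal":
        latent = rng.lognormal(mean=0.0, sigma=1.0, size=(p, d))
    elif rate_model == "equal_variance":
        latent = rng.normal(size=(p, d))
    else:
        raise ValueError(f"unknown rate_model {rate_model!r}")
    if smooth and smoothing_sd_ms > 0:
        latent = _gaussian_smooth(latent, smoothing_sd_ms / bin_ms)
    return latent


def linear_embed(
    latent: np.ndarray, n_ambient: int = DEFAULT_AMBIENT, seed: int = 0
) -> ManifoldSample:
    """Mix d latent channels into n_ambient >= d channels.

    The mixing matrix has iid standard normal entries; a linear map of full
    column rank preserves the intrinsic dimension (the ambient data have
    rank <= d).
    """
    latent = np.asarray(latent, dtype=float)
    d = latent.shape[1]
    if n_ambient < d:
        raise ValueError("n_ambient must be >= latent dimension")
    rng = np.random.default_rng(seed)
    mixing = rng.normal(size=(n_ambient, d))
    return ManifoldSample(
        points=latent @ mixing.T, true_id=d, generator_name="linear_embed",
        params={"d": d, "n_ambient": n_ambient, "seed": seed},
    )


def nonlinear_embed(
    data: ManifoldSample, alpha: float, scale_to_unit: bool = True
) -> ManifoldSample:
    """Coordinate-wise saturating exponential y = (e^{a x} - 1)/(e^a - 1).

    Monotone with fixed points y(0) = 0 and y(1) = 1, hence invertible and
    intrinsic-dimension preserving; alpha sets the skew (alpha -> 0 is the
    identity, taken by continuity).  Not an isometry: large alpha distorts
    neighborhood relations, which is the hard regime for ID estimators.

    ``scale_to_unit`` (default) min-max rescales each coordinate to [0, 1]
    — the map's natural domain, where its fixed points live — before the
    exponential.  Without it, mixed coordinates with variance ~ d would see
    an effective nonlinearity of alpha * sqrt(d) instead of alpha.  The
    affine rescaling is itself dimension-preserving.  Data already in
    [0, 1] (spanning both endpoints) pass through unchanged.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    x = data.points
    if scale_to_unit:
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        x = (x - lo) / span
    if alpha == 0.0:
        y = x.copy()
    else:
        y = np.expm1(alpha * x) / np.expm1(alpha)
    return ManifoldSample(
        points=y, true_id=data.true_id, generator_name="nonlinear_embed",
        params={**data.params, "alpha": alpha, "inner": data.generator_name},
    )


def repeated_stimulus_responses(
    d_signal: int,
    n_stim: int,
    n_neurons: int,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two repetitions sharing a rank-d_signal stimulus signal plus noise.

    Test bed for cross-validated PCA: the stimulus-driven part of the
    response is identical across repetitions while the noise is independent,
    so cross-repetition covariance isolates the signal subspace.
    """
    if d_signal > min(n_stim, n_neurons):
        raise ValueError("d_signal must be <= min(n_stim, n_neurons)")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_stim, d_signal))
    loadings = rng.normal(size=(d_signal, n_neurons))
    signal = factors @ loadings
    rep1 = signal + rng.normal(scale=noise_sd, size=signal.shape)
    rep2 = signal + rng.normal(scale=noise_sd, size=signal.shape)
    return rep1, rep2
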