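"""Comparison intrinsic-dimension estimators.

Linear methods (PCA variance threshold, participation ratio, parallel
analysis) measure the dimension of the minimal linear subspace containing
the data — the embedding dimension — which coincides with the intrinsic
dimension only for flat manifolds.  Geometric methods (correlation
dimension, max-likelihood k-NN, Two-NN) use distance scaling laws and work
on curved manifolds but suffer the curse of dimensionality, underestimating
large IDs.  ``cvpca_project`` isolates stimulus-related variance from two
repetitions of the same stimuli before any dimension analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .fci import _as_points

__all__ = [
    "corrdim",
    "covariance_spectrum",
    "cvpca_project",
    "mle_id",
    "parallel_analysis",
    "participation_ratio",
    "pca_id",
    "twonn",
    "twonn_decimated",
]


def covariance_spectrum(points: np.ndarray) -> np.ndarray:
    """Eigenvalues of the covariance matrix, non-increasing, >= 0."""
    pts = _as_points(points)
    x = pts - pts.mean(axis=0)
    # singular values of the centered data give the spectrum without forming
    # an N x N matrix when N >> P
    s = np.linalg.svd(x, compute_uv=False)
    lam = np.zeros(pts.shape[1])
    lam[: s.size] = s**2 / (pts.shape[0] - 1)
    return np.maximum(lam, 0.0)


def pca_id(points: np.ndarray, alpha: float = 0.95) -> int:
    """Minimal number of principal components holding >= alpha of variance."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lam = covariance_spectrum(points)
    total = lam.sum()
    if total == 0:
        return 0
    frac = np.cumsum(lam) / total
    # tolerance keeps exact-threshold cases (e.g. 8/10 >= 0.8) stable
    return int(np.searchsorted(frac, alpha - 1e-9) + 1)


def participation_ratio(points: np.ndarray) -> float:
    """Effective linear dimension 1 / sum_k (lambda_k / V)^2, in [1, N]."""
    lam = covariance_spectrum(points)
    total = lam.sum()
    if total == 0:
        raise ValueError("zero total variance")
    return float(1.0 / np.sum((lam / total) ** 2))


def parallel_analysis(
    points: np.ndarray,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> int:
    """Number of covariance eigenvalues exceeding a shuffled-data null.

    Surrogates shuffle each coordinate column independently, destroying
    correlations while keeping marginals.  The critical value is the
    (1 - alpha)*100th percentile of the pooled null eigenvalue
    distribution; the estimate is the largest K with lambda_K above it.
    """
    if n_shuffles < 10:
        raise ValueError("need at least 10 shuffles")
    pts = _as_points(points)
    lam = covariance_spectrum(pts)
    rng = np.random.default_rng(seed)
    null: list[np.ndarray] = []
    for _ in range(n_shuffles):
        surrogate = np.column_stack(
            [rng.permutation(pts[:, j]) for j in range(pts.shape[1])]
        )
        null.append(covariance_spectrum(surrogate))
    nu = float(np.percentile(np.concatenate(null), (1 - alpha) * 100))
    above = np.flatnonzero((lam >= nu) & (lam > 0))
    return int(above.max() + 1) if above.size else 0


def corrdim(
    points: np.ndarray,
    fit_window: tuple[float, float] = (0.01, 0.10),
) -> float:
    """Grassberger-Procaccia correlation dimension.

    Log-log slope of the empirical correlation integral over radii between
    the 1st and 10th percentile of pairwise distances (the small-r scaling
    window needs a finite lower edge at finite P).
    """
    from scipy.spatial.distance import pdist

    pts = _as_points(points, min_points=100)
    dists = np.sort(pdist(pts))
    dists = dists[dists > 0]
    lo, hi = np.quantile(dists, fit_window)
    radii = np.geomspace(max(lo, 1e-12), hi, 16)
    counts = np.searchsorted(dists, radii, side="right")
    ok = counts >= 10
    if ok.sum() < 4:
        raise ValueError("too few pairs in the small-radius fit window")
    rho = counts[ok] / dists.size
    slope = np.polyfit(np.log(radii[ok]), np.log(rho), 1)[0]
    return float(slope)


def _knn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point ascending distances to the k nearest (other) points."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    d, _ = nn.kneighbors(points)
    return d[:, 1:]


def mle_id(points: np.ndarray, K: int = 20) -> float:
    """Levina-Bickel maximum-likelihood intrinsic dimension.

    Per point, D_i = (K - 1) / sum_{k<K} log(r_{i,K} / r_{i,k}); the global
    value is the harmonic aggregate (inverse of the mean inverse), the
    standard bias-corrected convention.  Duplicate points (zero neighbor
    distances) are collapsed with a warning.
    """
    if K < 3:
        raise ValueError("K must be >= 3")
    pts = _as_points(points, min_points=K + 1)
    r = _knn_distances(pts, K)
    zero = r[:, 0] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} points have duplicate coordinates; "
            "collapsed before the MLE", stacklevel=2
        )
        pts = np.unique(pts, axis=0)
        if pts.shape[0] < K + 1:
            raise ValueError("too few distinct points after collapsing duplicates")
        r = _knn_distances(pts, K)
    inv = np.log(r[:, -1][:, None] / r[:, :-1]).sum(axis=1) / (K - 1)
    return float(1.0 / inv.mean())


def twonn(points: np.ndarray, discard_fraction: float = 0.1) -> float:
    """Two-NN estimator: Pareto fit of mu_i = r_{i,2} / r_{i,1}.

    Under local uniformity, mu follows Pareto(D):
    F(mu) = 1 - mu^{-D}.  D is obtained by linear regression of
    -log(1 - F_emp) on log mu through the origin after discarding the top
    ``discard_fraction`` of mu values (tail ratios violate the two-neighbor
    uniformity assumption most).  Duplicate points (r_1 = 0) are excluded.
    """
    if not 0 <= discard_fraction < 0.5:
        raise ValueError("discard_fraction must be in [0, 0.5)")
    pts = _as_points(points, min_points=100)
    r = _knn_distances(pts, 2)
    ok = r[:, 0] > 0
    n_dup = int((~ok).sum())
    if n_dup:
        warnings.warn(f"excluded {n_dup} duplicate points (r1 = 0)", stacklevel=2)
    mu = np.maximum(r[ok, 1] / r[ok, 0], 1.0)
    return _pareto_fit(mu, discard_fraction)


def _pareto_fit(mu: np.ndarray, discard_fraction: float) -> float:
    mu = np.sort(mu)
    n = mu.size
    keep = n - int(np.floor(discard_fraction * n))
    mu = mu[:keep]
    f_emp = np.arange(1, keep + 1) / (n + 1)
    x = np.log(mu)
    y = -np.log(1.0 - f_emp)
    pos = x > 0
    if pos.sum() < 10:
        raise ValueError("too few distinct neighbor ratios for the Two-NN fit")
    # least-squares slope through the origin
    return float((x[pos] @ y[pos]) / (x[pos] @ x[pos]))


def twonn_decimated(
    points: np.ndarray,
    fractions: np.ndarray | list[float] = (1.0, 0.5, 0.25, 0.125, 0.0625),
    n_rep: int = 5,
    seed: int = 0,
    discard_fraction: float = 0.1,
    plateau_tol: float = 0.05,
) -> float:
    """Two-NN on random subsamples of decreasing density.

    Decimation increases the typical nearest-neighbor distance, diluting the
    small-scale noise that inflates plain Two-NN.  Estimates are averaged
    over ``n_rep`` seeded subsamples per fraction; the reported value is the
    plateau of the estimate-vs-fraction curve: the largest fraction whose
    estimate differs by less than ``plateau_tol`` (relative) from the
    next-smaller fraction.  Fractions leaving fewer than 100 points are
    skipped with a warning.
    """
    pts = _as_points(points, min_points=100)
    fractions = sorted({float(f) for f in fractions}, reverse=True)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p = pts.shape[0]
    curve: list[tuple[float, float]] = []
    for f in fractions:
        n_sub = int(round(f * p))
        if n_sub < 100:
            warnings.warn(f"fraction {f} leaves {n_sub} < 100 points; skipped",
                          stacklevel=2)
            continue
        vals = []
        for _ in range(n_rep if f < 1.0 else 1):
            idx = rng.choice(p, size=n_sub, replace=False)
            vals.append(twonn(pts[idx], discard_fraction))
        curve.append((f, float(np.mean(vals))))
    if len(curve) < 2:
        return curve[0][1] if curve else float("nan")
    # plateau: largest fraction consistent with the next-smaller one
    for (f_hi, v_hi), (_, v_lo) in zip(curve[:-1], curve[1:]):
        if abs(v_hi - v_lo) / max(abs(v_lo), 1e-12) < plateau_tol:
            return v_hi
    return curve[-1][1]


def cvpca_project(
    responses_rep1: np.ndarray,
    responses_rep2: np.ndarray,
    variance_fraction: float = 0.99,
) -> np.ndarray:
    """Project onto the cross-validated-PCA stimulus-related subspace.

    Axes are ranked by the symmetrized cross-repetition covariance of the
    two stimulus-aligned response matrices (stimuli x neurons): independent
    noise has zero expected cross-covariance, so high-cross-covariance axes
    carry stimulus-related variance.  The data (average of the two
    repetitions) are projected onto the smallest leading subspace holding
    ``variance_fraction`` of the total positive cross-repetition variance.
    """
    a = _as_points(responses_rep1)
    b = _as_points(responses_rep2)
    if a.shape != b.shape:
        raise ValueError(f"repetition shapes differ: {a.shape} vs {b.shape}")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    n = a.shape[0] - 1
    cross = (a.T @ b + b.T @ a) / (2 * n)
    eigval, eigvec = np.linalg.eigh(cross)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # noise floor: independent noise makes the cross spectrum symmetric
    # around zero, so the magnitude of the most negative eigenvalue bounds
    # what noise alone produces on any axis
    floor = abs(float(eigval.min())) if eigval.min() < 0 else 0.0
    sig = eigval[eigval > floor]
    if sig.size == 0:
        n_keep = 1  # pure noise: nothing stimulus-related beyond one axis
    else:
        frac = np.cumsum(sig) / sig.sum()
        n_keep = int(np.searchsorted(frac, variance_fraction) + 1)
        n_keep = max(1, min(n_keep, sig.size))
    basis = eigvec[:, :n_keep]
    return (a + b) / 2 @ basis
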