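"""Global full-correlation-integral (FCI) intrinsic-dimension estimation.

The FCI estimator assumes points are sampled from a rotationally invariant
distribution on a ``d``-dimensional hyperplane.  After subtracting the center
of mass and normalizing every point to unit norm, such data lie on the unit
sphere :math:`S^{d-1}`, whose pair (chord) distance CDF has a closed form
valid at *all* radii, not just the small-``r`` scaling limit.  Fitting the
empirical correlation integral with this sigmoidal model yields an estimator
that remains accurate even when ``P < d`` (extreme undersampling).

The model here is parametrized directly by the hyperplane dimension ``d``
(the sphere is :math:`S^{d-1}`), so the reported dimension ``d_id`` equals
the fitted parameter: the conventional "+1" bookkeeping that compensates the
degree of freedom removed by normalization is folded into the
parametrization.  Self-consistency on data of known dimension (a uniform
2-D plane returns ~2, a circle the arcsine law) pins this convention down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betainc

__all__ = [
    "CorrelationIntegralCurve",
    "DegenerateInputError",
    "FCIFit",
    "center_and_normalize",
    "empirical_correlation_integral",
    "fci_model",
    "fit_fci",
]

#: Exact all-pairs counting is used up to this many points ...
EXACT_POINT_CAP = 20_000
#: ... above it, a seeded subsample of at most this many pairs.
MAX_SUBSAMPLED_PAIRS = 200_000_000

#: Number of radii in the default fit grid (equally spaced quantiles of the
#: normalized pairwise distances, from 0.5% to 100%).
N_RADII = 64

#: Dimension scan range for the coarse fit initialization.
D_SCAN = (1.0, 2000.0)

GOF_SENTINEL = np.inf


class DegenerateInputError(ValueError):
    """Raised when the input point cloud cannot be processed (e.g. a point
    coincides with the center of mass and cannot be normalized)."""


@dataclass(frozen=True)
class CorrelationIntegralCurve:
    """Empirical correlation integral: fraction of pairs within distance r."""

    radii: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        rho = np.asarray(self.rho, dtype=float)
        if radii.shape != rho.shape or radii.ndim != 1:
            raise ValueError("radii and rho must be 1-D arrays of equal length")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "rho", rho)


@dataclass(frozen=True)
class FCIFit:
    """Result of fitting the FCI model to an empirical correlation integral.

    Attributes
    ----------
    d_fit:
        Free dimension parameter of the sigmoidal model.
    d_id:
        Reported intrinsic dimension.  Equal to ``d_fit`` (the model is
        parametrized by the hyperplane dimension; see module docstring).
    gof:
        Goodness of fit: root-mean-squared deviation of the empirical
        correlation integral from the fitted model (larger = worse).
        ``inf`` flags a non-convergent fit.
    curve:
        The empirical (bias-corrected) correlation integral the model was
        fitted to.
    model_rho:
        Model values at ``curve.radii``.
    """

    d_fit: float
    d_id: float
    gof: float
    curve: CorrelationIntegralCurve
    model_rho: np.ndarray = field(repr=False)

    @property
    def converged(self) -> bool:
        return np.isfinite(self.gof)


def _as_points(points: np.ndarray, min_points: int = 2) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError(f"point cloud must be 2-D (P x N), got shape {pts.shape}")
    if pts.shape[0] < min_points:
        raise ValueError(f"need at least {min_points} points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise DegenerateInputError("point cloud contains non-finite entries")
    return pts


def center_and_normalize(points: np.ndarray) -> np.ndarray:
    """Subtract the center of mass and scale every point to unit norm.

    This is the first step of the FCI pipeline: it projects the cloud onto
    the unit sphere around its own barycenter, where the analytic model of
    the correlation integral applies.

    Raises
    ------
    DegenerateInputError
        If any point coincides with the center of mass (zero norm after
        centering), naming the offending row.
    """
    pts = _as_points(points)
    centered = pts - pts.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise DegenerateInputError(
            f"point(s) at row(s) {bad.tolist()} coincide with the center of "
            "mass and cannot be normalized"
        )
    return centered / norms[:, None]


def _pair_distances(
    points: np.ndarray,
    max_pairs: int | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """All pairwise distances, or a seeded uniform subsample of pairs.

    Exact counting is used whenever the number of pairs fits under the cap;
    above it, ``max_pairs`` pairs (i < j, without replacement in expectation)
    are drawn with the supplied generator.
    """
    p = points.shape[0]
    n_pairs = p * (p - 1) // 2
    if max_pairs is None or n_pairs <= max_pairs:
        from scipy.spatial.distance import pdist

        return pdist(points)
    if rng is None:
        rng = np.random.default_rng(0)
    i = rng.integers(0, p, size=max_pairs)
    j = rng.integers(0, p - 1, size=max_pairs)
    j = np.where(j >= i, j + 1, j)  # j != i, uniform over ordered pairs
    diff = points[i] - points[j]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def empirical_correlation_integral(
    points: np.ndarray,
    radii: np.ndarray,
    *,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> CorrelationIntegralCurve:
    """Fraction of point pairs within each cutoff radius.

    rho(r) = 2 / (P (P-1)) * #{pairs i<j : ||x_i - x_j|| <= r}.

    Counting is exact over all pairs unless ``max_pairs`` caps the number of
    (seeded) sampled pairs; the curve is then an unbiased estimate with
    standard error <= 0.5 / sqrt(max_pairs).
    """
    pts = _as_points(points)
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or radii.size == 0:
        raise ValueError("radii must be a non-empty 1-D array")
    if np.any(np.diff(radii) < 0) or np.any(radii < 0):
        raise ValueError("radii must be ascending and non-negative")
    rng = np.random.default_rng(seed) if seed is not None else None
    dists = np.sort(_pair_distances(pts, max_pairs, rng))
    rho = np.searchsorted(dists, radii, side="right") / dists.size
    return CorrelationIntegralCurve(radii=radii, rho=rho)


def fci_model(r: float | np.ndarray, d: float) -> float | np.ndarray:
    """Average correlation integral of a uniform sample on :math:`S^{d-1}`.

    Closed form: the chord-distance CDF
    :math:`\\rho(r) = I_{r^2/4}\\left(\\tfrac{d-1}{2}, \\tfrac{d-1}{2}\\right)`
    (regularized incomplete beta function), a sigmoid in ``r`` on [0, 2] with
    midpoint at ``sqrt(2)`` and slope growing with ``d``.  For ``d = 2`` it
    reduces to the circle law ``(2/pi) arcsin(r/2)``; equivalent to the usual
    Gauss-hypergeometric expression of the full correlation integral.

    Parameters
    ----------
    r:
        Chord distance(s) in [0, 2].
    d:
        Hyperplane dimension, >= 1 (d = 1 is the two-point sphere
        :math:`S^0`, a step at 0/2 whose CDF is 1/2 on (0, 2)).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > 2):
        raise ValueError("chord distances must lie in [0, 2]")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    a = max((d - 1.0) / 2.0, 1e-8)
    out = betainc(a, a, np.clip(r_arr**2 / 4.0, 0.0, 1.0))
    return float(out) if np.isscalar(r) else out


def _fit_curve(radii: np.ndarray, rho: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Fit the dimension of the FCI model to an empirical curve.

    Coarse log-spaced scan over d (vectorized over the whole grid; the
    residual surface can be flat and multi-modal at high d) followed by a
    bounded scalar refinement between the best scan point's neighbors.
    Returns (d, gof, model_rho); a failed fit returns gof = inf.
    """
    x = np.clip(radii**2 / 4.0, 0.0, 1.0)

    def rms_at(logd: float) -> float:
        a = max((np.exp(logd) - 1.0) / 2.0, 1e-8)
        return float(np.sqrt(np.mean((betainc(a, a, x) - rho) ** 2)))

    d_grid = np.geomspace(D_SCAN[0] + 0.05, D_SCAN[1], 400)
    a_grid = np.maximum((d_grid - 1.0) / 2.0, 1e-8)[:, None]
    scan = betainc(a_grid, a_grid, x[None, :])
    rms = np.sqrt(np.mean((scan - rho[None, :]) ** 2, axis=1))
    i = int(np.argmin(rms))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = minimize_scalar(
                rms_at,
                bounds=(np.log(d_grid[max(i - 1, 0)]), np.log(d_grid[min(i + 1, d_grid.size - 1)])),
                method="bounded",
            )
    except Exception:
        return np.nan, GOF_SENTINEL, np.full_like(rho, np.nan)
    d = float(np.exp(sol.x))
    a = max((d - 1.0) / 2.0, 1e-8)
    model_rho = betainc(a, a, x)
    gof = float(np.sqrt(np.mean((model_rho - rho) ** 2)))
    if not (np.isfinite(d) and np.isfinite(gof)) or d < 0.5:
        return np.nan, GOF_SENTINEL, model_rho
    return d, gof, model_rho


def fit_fci(
    points: np.ndarray,
    *,
    n_radii: int = N_RADII,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> FCIFit:
    """Global FCI intrinsic-dimension estimate of a point cloud.

    The cloud is centered and normalized, the empirical correlation integral
    is measured at ``n_radii`` radii placed at equally spaced quantiles
    (0.5%..100%) of the pairwise distances, and the sphere model is fitted
    by least squares with the dimension as the only free parameter.

    A finite-sample correction is applied to the squared chord distances
    before fitting: subtracting the sample mean of P isotropic points makes
    pair cosines average -1/(P-1) rather than 0, so squared distances are
    shifted by -2/(P-1).  Without it the whole distance distribution sits
    right of the model midpoint sqrt(2) and the fit absorbs the shift as a
    severe dimension underestimate in the undersampled regime (P ~ tens,
    d ~ hundreds); with it, 20 Gaussian points in 200 dimensions are
    recovered to a few percent.

    Parameters
    ----------
    points:
        P x N array, P >= 5.
    max_pairs:
        Optional cap on the number of pairs used (seeded subsample above the
        cap).  By default, counting is exact up to ``EXACT_POINT_CAP`` points
        and subsampled at ``MAX_SUBSAMPLED_PAIRS`` pairs beyond.
    seed:
        Seed for pair subsampling (only relevant when a cap is active).
    """
    pts = _as_points(points, min_points=5)
    p = pts.shape[0]
    if max_pairs is None and p > EXACT_POINT_CAP:
        max_pairs = MAX_SUBSAMPLED_PAIRS
    unit = center_and_normalize(pts)
    rng = np.random.default_rng(seed) if seed is not None else None
    raw = _pair_distances(unit, max_pairs, rng)
    # finite-sample centering correction on squared chords (see docstring)
    dists = np.sort(np.sqrt(np.clip(raw**2 - 2.0 / (p - 1), 0.0, 4.0)))
    qs = np.linspace(0.005, 1.0, n_radii)
    radii = np.quantile(dists, qs)
    rho = np.searchsorted(dists, radii, side="right") / dists.size
    curve = CorrelationIntegralCurve(radii=radii, rho=rho)
    d, gof, model_rho = _fit_curve(radii, rho)
    return FCIFit(d_fit=d, d_id=d, gof=gof, curve=curve, model_rho=model_rho)
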