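"""The local FCI (lFCI) pipeline.

Global FCI overestimates the intrinsic dimension of curved manifolds (it is
exact only for isotropically sampled hyperplanes).  The local pipeline fixes
this by fitting FCI on k-nearest-neighbor patches, which approximate the
tangent plane, across a grid of neighborhood sizes K:

1. compute local estimates ``D_{i,K}`` on M randomly selected neighborhoods
   for each K in the grid;
2. compute the GoF acceptance threshold ``gamma`` from the per-K GoF
   distributions (99th percentile rule);
3. discard estimates with sizable curvature (``delta > 2``) or comparatively
   poor fit quality (``GoF > gamma``);
4. collect the surviving local estimates in a histogram and report its mode
   ``D*`` as the overall intrinsic dimension;
5. report the 10th and 90th percentiles of the retained local estimates as a
   plausibility band.

``delta`` is the curvature proxy: the distance from a neighborhood's center
of mass to its closest member, normalized by the mean nearest-neighbor
spacing inside the neighborhood.  Flat patches give delta ~ 1; for a curved
patch the center of mass is displaced off the manifold (for a full sphere it
sits at the center, far from every surface point), making delta large.
Calibration on flat data of various dimensions and anisotropies shows delta
stays below 2 with near certainty, so delta > 2 is a conservative curvature
flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .fci import FCIFit, GOF_SENTINEL, _as_points, fit_fci

__all__ = [
    "IDReport",
    "LocalEstimate",
    "Neighborhood",
    "NoReliableEstimatesError",
    "default_k_grid",
    "delta",
    "filter_reliable",
    "gof_threshold",
    "id_histogram_report",
    "knn_neighborhood",
    "lfci",
    "local_fci",
    "multiscale_estimates",
    "select_centers",
]

logger = logging.getLogger(__name__)

DELTA_MAX = 2.0          # curvature acceptance bound on delta
GOF_PERCENTILE = 99.0    # per-K GoF percentile defining gamma
LOCAL_MAX_PAIRS = 300_000  # seeded pair-subsample cap for local fits
DELTA_MAX_ANCHORS = 512  # exact NN spacing up to this K, anchor estimate above
MIN_RELIABLE = 10        # fewer reliable estimates -> low-confidence report


class NoReliableEstimatesError(RuntimeError):
    """Every local estimate was discarded by the delta/GoF filters.

    Revisit the K grid (smaller neighborhoods resolve curvature better) or
    the GoF-threshold variant before trusting any global number.
    """


@dataclass(frozen=True)
class Neighborhood:
    """The K nearest neighbors of one center point (center excluded)."""

    center_index: int
    K: int
    member_indices: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.member_indices.shape[0] != self.K or self.points.shape[0] != self.K:
            raise ValueError("neighborhood must contain exactly K members")


@dataclass(frozen=True)
class LocalEstimate:
    """Local FCI record for one (center, K) pair."""

    center_index: int
    K: int
    d_local: float
    delta: float
    gof: float
    reliable: bool | None = None


@dataclass(frozen=True)
class IDReport:
    """Aggregated lFCI estimate.

    ``d_star`` is the mode of the histogram of retained local estimates;
    ``[p10, p90]`` the percentile band of the same values.  ``caveat`` is
    set on low-confidence paths (too few or no reliable local estimates).
    """

    d_star: float
    p10: float
    p90: float
    n_reliable: int
    n_total: int
    K_grid: tuple[int, ...]
    gof_threshold: float
    caveat: str | None = None


def default_k_grid(p: int, n_scales: int = 12, k_min: int = 50, k_max: int = 10_000) -> np.ndarray:
    """Log-spaced neighborhood sizes from ``k_min`` to ``min(p // 2, k_max)``.

    The grid stops at half the dataset: a "neighborhood" containing most of
    the points is no longer local — it duplicates the global fit, and its
    (often excellent) GoF would poison the GoF-threshold rule while its
    curvature statistic already disqualifies it on curved data.
    """
    hi = min(p // 2, k_max)
    if hi < 5:
        raise ValueError(f"too few points ({p}) for a local analysis")
    lo = min(k_min, hi)
    grid = np.unique(np.geomspace(lo, hi, n_scales).round().astype(int))
    return grid


def select_centers(points: np.ndarray, m: int, seed: int) -> np.ndarray:
    """M distinct center indices, uniform without replacement, seed-stable."""
    pts = _as_points(points)
    p = pts.shape[0]
    if not 1 <= m <= p:
        raise ValueError(f"number of centers m={m} must be in [1, {p}]")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(p, size=m, replace=False))


def _neighbor_order(points: np.ndarray, center_index: int) -> np.ndarray:
    """All other indices sorted by distance to the center; ties by index.

    Stable sort on distances gives a deterministic index tie-break, so
    duplicate points are retained in index order.
    """
    d = np.linalg.norm(points - points[center_index], axis=1)
    order = np.argsort(d, kind="stable")
    return order[order != center_index]


def knn_neighborhood(points: np.ndarray, center_index: int, K: int) -> Neighborhood:
    """Exact K-nearest-neighbor set of one center (center itself excluded)."""
    pts = _as_points(points)
    p = pts.shape[0]
    if not 0 <= center_index < p:
        raise IndexError(f"center index {center_index} out of range")
    if not 2 <= K <= p - 1:
        raise ValueError(f"K={K} must be in [2, {p - 1}]")
    members = _neighbor_order(pts, center_index)[:K]
    return Neighborhood(
        center_index=int(center_index), K=int(K),
        member_indices=members, points=pts[members],
    )


def _delta_from_points(
    pts: np.ndarray, rng: np.random.Generator | None = None
) -> float:
    """delta = min_j ||b - x_j|| / mean_j min_{k != j} ||x_j - x_k||.

    The numerator is exact.  The denominator (mean nearest-neighbor spacing)
    is exact for K <= DELTA_MAX_ANCHORS and estimated from that many seeded
    anchor members above (standard error of the mean, a few percent).
    """
    k, n = pts.shape
    b = pts.mean(axis=0)
    num = float(np.min(np.linalg.norm(pts - b, axis=1)))
    if k <= DELTA_MAX_ANCHORS or n <= 15:
        if n <= 15 and k > 64:
            tree = cKDTree(pts)
            nn = tree.query(pts, k=2)[0][:, 1]
        else:
            d2 = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            np.fill_diagonal(d2, np.inf)
            nn = d2.min(axis=1)
        denom = float(nn.mean())
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        anchors = rng.choice(k, size=DELTA_MAX_ANCHORS, replace=False)
        d2 = np.einsum("ij,ij->i", pts, pts)
        cross = pts[anchors] @ pts.T
        dist2 = d2[anchors][:, None] - 2 * cross + d2[None, :]
        dist2[np.arange(anchors.size), anchors] = np.inf
        nn = np.sqrt(np.maximum(dist2.min(axis=1), 0.0))
        denom = float(nn.mean())
    if denom == 0.0:
        raise ValueError("degenerate neighborhood: all points identical")
    return num / denom


def delta(nbhd: Neighborhood, seed: int | None = None) -> float:
    """Curvature proxy of a neighborhood (see module docstring)."""
    if nbhd.K < 3:
        raise ValueError("delta needs K >= 3")
    rng = np.random.default_rng(seed) if seed is not None else None
    return _delta_from_points(nbhd.points, rng)


def local_fci(
    nbhd: Neighborhood,
    *,
    max_pairs: int | None = LOCAL_MAX_PAIRS,
    seed: int | None = None,
) -> LocalEstimate:
    """Fit FCI on one neighborhood (centered on its own center of mass).

    The fit is performed on the neighborhood's member points; re-centering
    happens inside :func:`~neurodim.fci.fit_fci`, so the isotropy assumption
    is applied to the sampled patch rather than to the query point.
    """
    if nbhd.K < 5:
        raise ValueError("local FCI needs K >= 5")
    fit: FCIFit = fit_fci(nbhd.points, max_pairs=max_pairs, seed=seed)
    dl = _delta_from_points(
        nbhd.points, np.random.default_rng(seed) if seed is not None else None
    )
    return LocalEstimate(
        center_index=nbhd.center_index, K=nbhd.K,
        d_local=fit.d_id, delta=dl, gof=fit.gof,
    )


def multiscale_estimates(
    points: np.ndarray,
    K_grid: np.ndarray | list[int],
    m: int,
    seed: int,
    *,
    max_pairs: int | None = LOCAL_MAX_PAIRS,
) -> list[LocalEstimate]:
    """One local estimate per (center, K) pair: M * len(K_grid) records.

    Neighborhoods are nested across K for each center, so the neighbor
    ordering is computed once per center.  Fully reproducible for a fixed
    (points, K_grid, m, seed).
    """
    pts = _as_points(points)
    K_grid = np.asarray(K_grid, dtype=int)
    if K_grid.size == 0:
        raise ValueError("K_grid must not be empty")
    if np.any(np.diff(K_grid) < 0):
        raise ValueError("K_grid must be ascending")
    if K_grid.max() > pts.shape[0] - 1:
        raise ValueError("max(K_grid) must be <= P - 1")
    centers = select_centers(pts, m, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    estimates: list[LocalEstimate] = []
    for ci in centers:
        order = _neighbor_order(pts, ci)
        for K in K_grid:
            sub = pts[order[:K]]
            fit = fit_fci(
                sub, max_pairs=max_pairs,
                seed=int(rng.integers(2**31)),
            )
            dl = _delta_from_points(sub, rng)
            estimates.append(
                LocalEstimate(
                    center_index=int(ci), K=int(K),
                    d_local=fit.d_id, delta=dl, gof=fit.gof,
                )
            )
    logger.info(
        "multiscale estimates: %d centers x %d scales = %d records",
        centers.size, K_grid.size, len(estimates),
    )
    return estimates


def gof_threshold(
    estimates: list[LocalEstimate], variant: str = "min99"
) -> float:
    """GoF acceptance threshold gamma from the per-K GoF distributions.

    ``variant="min99"`` (default): the smallest 99th percentile across the
    per-K groups.  ``variant="best_median"``: the 99th percentile at the
    scale whose GoF distribution has the lowest median.  Non-convergent
    fits (infinite GoF) are ignored when computing percentiles.

    Only scales whose median delta is within the curvature bound contribute
    to the reference: on curved manifolds the largest neighborhoods
    approach the (smooth, well-fitting, but wrong) global fit, and letting
    a curvature-condemned scale define the fit-quality bar would discard
    every genuinely local estimate.  On flat data every scale qualifies
    and the rule reduces to the plain per-K percentile rule.
    """
    if not estimates:
        raise ValueError("no estimates")
    delta_by_k: dict[int, list[float]] = {}
    for e in estimates:
        delta_by_k.setdefault(e.K, []).append(e.delta)
    flat_scales = {
        k for k, v in delta_by_k.items() if np.median(v) <= DELTA_MAX
    } or set(delta_by_k)  # extreme curvature everywhere: use all scales
    by_k: dict[int, list[float]] = {}
    for e in estimates:
        if np.isfinite(e.gof) and e.K in flat_scales:
            by_k.setdefault(e.K, []).append(e.gof)
    if not by_k:
        return GOF_SENTINEL
    p99 = {k: float(np.percentile(v, GOF_PERCENTILE)) for k, v in by_k.items()}
    if variant == "min99":
        return min(p99.values())
    if variant == "best_median":
        medians = {k: float(np.median(v)) for k, v in by_k.items()}
        k_best = min(medians, key=medians.get)
        return p99[k_best]
    raise ValueError(f"unknown gof_threshold variant {variant!r}")


def filter_reliable(
    estimates: list[LocalEstimate], gamma: float
) -> list[LocalEstimate]:
    """Flag each estimate and return those with delta <= 2 and GoF <= gamma."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    flagged = [
        replace(e, reliable=bool(e.delta <= DELTA_MAX and e.gof <= gamma))
        for e in estimates
    ]
    estimates[:] = flagged
    kept = [e for e in flagged if e.reliable]
    logger.info("reliability filter: kept %d / %d estimates", len(kept), len(flagged))
    if not kept:
        raise NoReliableEstimatesError(
            "all local estimates were discarded (delta > 2 or GoF > gamma); "
            "revisit the K grid or the GoF-threshold variant"
        )
    return kept


def _histogram_mode(values: np.ndarray) -> tuple[float, float]:
    """Mode of the local-ID histogram; ties broken toward lower ID.

    Freedman-Diaconis bin width (2 IQR / n^(1/3)): narrow enough to localize
    a tight unimodal peak to a few hundredths of a dimension, wide enough to
    resolve integer-separated peaks with O(100) estimates.  Degenerate
    spreads fall back to the exact dominant value.
    """
    q25, q75 = np.percentile(values, [25, 75])
    width = 2.0 * (q75 - q25) / values.size ** (1.0 / 3.0)
    if width <= 0:
        vals, counts = np.unique(values, return_counts=True)
        return float(vals[np.argmax(counts)]), 0.0
    lo = values.min() - 0.5 * width
    n_bins = max(1, int(np.ceil((values.max() - lo) / width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * width))
    i = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    return float(0.5 * (edges[i] + edges[i + 1])), width


def id_histogram_report(
    reliable: list[LocalEstimate],
    K_grid: tuple[int, ...] | None = None,
    gamma: float = np.nan,
) -> IDReport:
    """Aggregate retained local estimates: histogram mode and [p10, p90]."""
    if not reliable:
        raise ValueError("no reliable estimates to aggregate")
    vals = np.array([e.d_local for e in reliable if np.isfinite(e.d_local)])
    if vals.size == 0:
        raise ValueError("no finite local estimates to aggregate")
    caveat = None
    if vals.size < MIN_RELIABLE:
        caveat = f"only {vals.size} reliable estimates; low-confidence report"
        warnings.warn(caveat, stacklevel=2)
    d_star, _ = _histogram_mode(vals)
    p10, p90 = np.percentile(vals, [10, 90])
    if K_grid is None:
        K_grid = tuple(sorted({e.K for e in reliable}))
    return IDReport(
        d_star=d_star, p10=float(p10), p90=float(p90),
        n_reliable=vals.size, n_total=vals.size,
        K_grid=tuple(int(k) for k in K_grid),
        gof_threshold=float(gamma), caveat=caveat,
    )


def lfci(
    points: np.ndarray,
    *,
    K_grid: np.ndarray | list[int] | None = None,
    m: int = 100,
    seed: int = 0,
    gof_variant: str = "min99",
    max_pairs: int | None = LOCAL_MAX_PAIRS,
    return_estimates: bool = False,
) -> IDReport | tuple[IDReport, list[LocalEstimate]]:
    """Run the full 5-step local-FCI pipeline on a point cloud.

    Parameters
    ----------
    points:
        P x N point cloud.
    K_grid:
        Neighborhood sizes; default 12 log-spaced integers from 50 to
        min(P - 1, 10^4).
    m:
        Number of randomly selected centers (default 100, which covers a
        10^4-point dataset even at small K).
    seed:
        Controls center selection and pair subsampling.
    gof_variant:
        GoF-threshold rule, see :func:`gof_threshold`.

    If every estimate is discarded by the filters, the global FCI estimate
    is reported instead, with an explicit caveat flag.
    """
    pts = _as_points(points)
    if K_grid is None:
        K_grid = default_k_grid(pts.shape[0])
    estimates = multiscale_estimates(pts, K_grid, m, seed, max_pairs=max_pairs)
    gamma = gof_threshold(estimates, variant=gof_variant)
    logger.info("GoF threshold gamma = %.4g (%s)", gamma, gof_variant)
    try:
        kept = filter_reliable(estimates, gamma)
        report = id_histogram_report(
            kept, K_grid=tuple(int(k) for k in np.asarray(K_grid)), gamma=gamma
        )
        report = replace(report, n_total=len(estimates))
    except NoReliableEstimatesError:
        fit = fit_fci(pts, seed=seed)
        report = IDReport(
            d_star=fit.d_id, p10=np.nan, p90=np.nan,
            n_reliable=0, n_total=len(estimates),
            K_grid=tuple(int(k) for k in np.asarray(K_grid)),
            gof_threshold=float(gamma),
            caveat="no reliable local estimates at any scale; reporting the "
                   "global FCI estimate (curvature filters could not be applied)",
        )
    if return_estimates:
        return report, estimates
    return report
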