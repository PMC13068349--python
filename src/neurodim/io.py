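"""File formats, run configuration, and report assembly.

Point clouds travel as delimited text (comma or tab, optional header) or
the ``.npy`` binary array container.  Estimation results are serialized as
JSON reports keyed by method, with TSV side tables for the multiscale
local-estimate records and local-ID histograms.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import baselines, fci, pipeline

__all__ = [
    "ComparisonReport",
    "RunConfig",
    "histogram_table",
    "read_point_cloud",
    "render_multiscale_table",
    "run_estimate",
    "write_point_cloud",
]

SCHEMA_VERSION = "1"

METHODS = ("pca", "pr", "pa", "corrdim", "mle", "twonn", "twonn-dec", "fci", "lfci")


@dataclass
class RunConfig:
    """Configuration of one estimation run; unknown keys are rejected."""

    method: str
    input: str | None = None
    seed: int = 0
    out: str | None = None
    params: dict[str, Any] = field(default_factory=dict)

    _KNOWN_PARAMS = {
        "m", "K_grid", "alpha", "n_shuffles", "K", "discard_fraction",
        "fractions", "n_rep", "gof_variant", "max_pairs",
    }

    def __post_init__(self) -> None:
        methods = METHODS + ("all",)
        if self.method not in methods:
            raise ValueError(f"unknown method {self.method!r}; choose from {methods}")
        unknown = set(self.params) - self._KNOWN_PARAMS
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class ComparisonReport:
    """Per-method estimates plus dataset provenance; JSON round-trippable."""

    entries: dict[str, dict[str, Any]]
    provenance: dict[str, Any]
    seed: int
    schema_version: str = SCHEMA_VERSION

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(asdict(self), default=_json_default, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls(**json.loads(text))


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_point_cloud(path: str | Path, fmt: str = "auto") -> np.ndarray:
    """Load a P x N point cloud from delimited text or a .npy container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "binary" if path.suffix == ".npy" else "delimited"
    if fmt == "binary":
        arr = np.load(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a 2-D array, got shape {arr.shape}")
        return np.asarray(arr, dtype=float)
    if fmt != "delimited":
        raise ValueError(f"unknown format {fmt!r}")
    # sniff delimiter and optional header
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#")
        if df.iloc[0].map(lambda v: isinstance(v, str)).any():
            df = pd.read_csv(path, sep=sep, header=0, comment="#")
        arr = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse point cloud ({exc})") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected rows of equal length")
    return arr


def write_point_cloud(path: str | Path, points: np.ndarray, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = "binary" if path.suffix == ".npy" else "delimited"
    if fmt == "binary":
        np.save(path, np.asarray(points, dtype=float))
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        np.savetxt(path, np.asarray(points, dtype=float), delimiter=sep)


def render_multiscale_table(estimates: list[pipeline.LocalEstimate]) -> pd.DataFrame:
    """Records behind the multiscale ID plot, sorted by (K, center)."""
    if not estimates:
        raise ValueError("no estimates to render")
    df = pd.DataFrame(
        [
            {
                "center": e.center_index, "K": e.K, "d_local": e.d_local,
                "delta": e.delta, "gof": e.gof, "reliable": e.reliable,
            }
            for e in estimates
        ]
    )
    return df.sort_values(["K", "center"], kind="stable").reset_index(drop=True)


def histogram_table(
    estimates: list[pipeline.LocalEstimate], bin_width: float = 0.25
) -> pd.DataFrame:
    """Local-ID histogram: bin_center, count_all, count_reliable."""
    vals = np.array([e.d_local for e in estimates if np.isfinite(e.d_local)])
    if vals.size == 0:
        raise ValueError("no finite local estimates")
    lo = np.floor(vals.min() / bin_width) * bin_width
    edges = np.arange(lo, vals.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    count_all, _ = np.histogram(vals, bins=edges)
    rel = np.array(
        [e.d_local for e in estimates if e.reliable and np.isfinite(e.d_local)]
    )
    count_rel, _ = np.histogram(rel, bins=edges)
    return pd.DataFrame(
        {
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "count_all": count_all,
            "count_reliable": count_rel,
        }
    )


def _run_single(method: str, points: np.ndarray, seed: int, params: dict) -> dict:
    t0 = time.perf_counter()
    entry: dict[str, Any] = {"method": method}
    if method == "pca":
        entry["estimate"] = baselines.pca_id(points, alpha=params.get("alpha", 0.95))
    elif method == "pr":
        entry["estimate"] = baselines.participation_ratio(points)
    elif method == "pa":
        entry["estimate"] = baselines.parallel_analysis(
            points, n_shuffles=params.get("n_shuffles", 100),
            alpha=params.get("alpha", 0.05), seed=seed,
        )
    elif method == "corrdim":
        entry["estimate"] = baselines.corrdim(points)
    elif method == "mle":
        entry["estimate"] = baselines.mle_id(points, K=params.get("K", 20))
    elif method == "twonn":
        entry["estimate"] = baselines.twonn(
            points, discard_fraction=params.get("discard_fraction", 0.1)
        )
    elif method == "twonn-dec":
        entry["estimate"] = baselines.twonn_decimated(
            points, fractions=params.get("fractions", (1.0, 0.5, 0.25, 0.125)),
            n_rep=params.get("n_rep", 5), seed=seed,
        )
    elif method == "fci":
        fit = fci.fit_fci(points, seed=seed)
        entry["estimate"] = fit.d_id
        entry["gof"] = fit.gof
    elif method == "lfci":
        report, estimates = pipeline.lfci(
            points,
            K_grid=params.get("K_grid"),
            m=params.get("m", 100),
            seed=seed,
            gof_variant=params.get("gof_variant", "min99"),
            max_pairs=params.get("max_pairs", pipeline.LOCAL_MAX_PAIRS),
            return_estimates=True,
        )
        entry["estimate"] = report.d_star
        entry["range"] = [report.p10, report.p90]
        entry["n_reliable"] = report.n_reliable
        entry["n_total"] = report.n_total
        entry["gof_threshold"] = report.gof_threshold
        if report.caveat:
            entry["caveat"] = report.caveat
        entry["_estimates"] = estimates
    else:
        raise ValueError(f"unknown method {method!r}")
    entry["runtime_s"] = round(time.perf_counter() - t0, 3)
    entry["parameters"] = dict(params)
    return entry


def run_estimate(
    config: RunConfig,
    points: np.ndarray | None = None,
    provenance: dict[str, Any] | None = None,
) -> ComparisonReport:
    """Dispatch to the configured estimator(s) and assemble a report.

    A failing estimator contributes an error-status entry; the run
    continues for the remaining methods.
    """
    if points is None:
        if config.input is None:
            raise ValueError("either points or config.input must be given")
        points = read_point_cloud(config.input)
        if provenance is None:
            import hashlib

            provenance = {
                "input": str(config.input),
                "sha256": hashlib.sha256(points.tobytes()).hexdigest()[:16],
            }
    provenance = provenance or {}
    provenance.setdefault("shape", list(points.shape))
    methods = list(METHODS) if config.method == "all" else [config.method]
    entries: dict[str, dict[str, Any]] = {}
    side_tables: dict[str, pd.DataFrame] = {}
    for method in methods:
        try:
            entry = _run_single(method, points, config.seed, config.params)
            ests = entry.pop("_estimates", None)
            if ests is not None:
                side_tables["multiscale"] = render_multiscale_table(ests)
                side_tables["histogram"] = histogram_table(ests)
            entries[method] = entry
        except Exception as exc:  # keep going: one bad method must not kill the run
            entries[method] = {"method": method, "status": "error", "error": str(exc)}
    report = ComparisonReport(entries=entries, provenance=provenance, seed=config.seed)
    if config.out:
        out = Path(config.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(report.to_json(indent=2))
        for name, df in side_tables.items():
            df.to_csv(out.with_name(f"{out.stem}_{name}.tsv"), sep="\t", index=False)
    return report
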