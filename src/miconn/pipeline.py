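"""End-to-end orchestration: ingestion, preprocessing, and the full analysis.

Input is a manifest CSV (``subject_id,path,iq``) pointing at per-subject
node x time TSV matrices.  For each subject the pipeline drops the initial
equilibration volumes, applies an optional frequency-domain high-pass
(default cutoff 0.01 Hz, i.e. a 100 s period at the 2 s repetition time),
builds both connectivity matrices, computes the four graph metrics, and then
fits the repeated-run random forest and the paired comparison statistics.
Every artifact is written under an output directory together with a
provenance record (config hash, seeds, library versions), and identical
inputs/seeds yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    MiConfig,
    TimeSeriesMatrix,
    connectivity_matrix,
    write_connectivity,
)
from .graph_metrics import METRIC_NAMES, WeightedGraph, subject_metrics
from .prediction import (
    CohortFeatures,
    compare_absolute_errors,
    compare_graph_metrics,
    repeated_runs,
    spearman_bonferroni,
)

__all__ = [
    "ManifestEntry",
    "RunConfig",
    "read_manifest",
    "read_timeseries",
    "write_timeseries",
    "preprocess_timeseries",
    "run_all",
]

logger = logging.getLogger("miconn")

METHODS = ("pearson_abs", "grid_mi")


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    timeseries_path: Path
    iq: float


@dataclass(frozen=True)
class RunConfig:
    """Reproducible run configuration for the whole pipeline."""

    mi: MiConfig = field(default_factory=MiConfig)
    drop_initial_volumes: int = 5
    highpass_hz: float | None = 0.01
    tr_seconds: float = 2.0
    n_trees: int = 500
    n_runs: int = 500
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.drop_initial_volumes < 0:
            raise ValueError("drop_initial_volumes must be >= 0")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.highpass_hz is not None:
            nyquist = 0.5 / self.tr_seconds
            if not 0 < self.highpass_hz < nyquist:
                raise ValueError(f"highpass_hz must lie in (0, {nyquist}) for this TR")
        if self.n_trees < 1 or self.n_runs < 1:
            raise ValueError("n_trees and n_runs must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mi"]["multiples"] = list(d["mi"]["multiples"])
        return d


def read_manifest(path) -> list[ManifestEntry]:
    """Read and validate the subject manifest CSV (subject_id, path, iq)."""
    df = pd.read_csv(path)
    required = {"subject_id", "path", "iq"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    ids = df["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate subject_ids {dupes}")
    if not np.isfinite(df["iq"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: IQ values must be finite")
    base = Path(path).parent
    entries = []
    for row in df.itertuples(index=False):
        p = Path(str(row.path))
        if not p.is_absolute():
            p = base / p
        entries.append(ManifestEntry(str(row.subject_id), p, float(row.iq)))
    return entries


def read_timeseries(path) -> TimeSeriesMatrix:
    """Read a node x time delimited text matrix (nodes in rows).

    A non-numeric first field on a row is taken as that node's id; otherwise
    ids are synthesised as n000, n001, ...  Ragged or non-numeric rows raise
    a parse error naming the line.
    """
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            try:
                float(parts[0])
                nid = None
                vals = parts
            except ValueError:
                nid = parts[0]
                vals = parts[1:]
            try:
                row = [float(v) for v in vals]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value on line {lineno}: {exc}")
            if rows and len(row) != len(rows[-1]):
                raise ValueError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} values, expected {len(rows[-1])})"
                )
            rows.append(row)
            ids.append(nid if nid is not None else f"n{len(rows) - 1:03d}")
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 node rows")
    return TimeSeriesMatrix(values=np.asarray(rows), node_ids=tuple(ids))


def write_timeseries(ts: TimeSeriesMatrix, path) -> None:
    """Write a node x time matrix as TSV with leading node ids."""
    with open(path, "w") as fh:
        for nid, row in zip(ts.node_ids, ts.values):
            fh.write(nid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def preprocess_timeseries(
    ts: TimeSeriesMatrix, config: RunConfig, tr_seconds: float | None = None
) -> TimeSeriesMatrix:
    """Drop initial volumes and apply the ideal frequency-domain high-pass.

    Fourier components strictly below the cutoff are removed and each node's
    mean is restored, so only slow drift is discarded.
    """
    tr = config.tr_seconds if tr_seconds is None else tr_seconds
    k = config.drop_initial_volumes
    if ts.n_timepoints <= k:
        raise ValueError(
            f"series of length {ts.n_timepoints} too short to drop {k} volumes"
        )
    vals = ts.values[:, k:]
    if config.highpass_hz is not None:
        t = vals.shape[1]
        spec = np.fft.rfft(vals, axis=1)
        freqs = np.fft.rfftfreq(t, d=tr)
        means = vals.mean(axis=1, keepdims=True)
        spec[:, freqs < config.highpass_hz] = 0.0
        vals = np.fft.irfft(spec, n=t, axis=1) + means
    return TimeSeriesMatrix(values=vals, node_ids=ts.node_ids)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _report_to_dict(report) -> dict:
    return {
        "method": report.method,
        "fve_mean": report.fve_mean,
        "fve_ci": list(report.fve_ci),
        "mae_mean": report.mae_mean,
        "mae_sd": report.mae_sd,
        "importance": {k: float(v) for k, v in zip(METRIC_NAMES, report.importance)},
        "n_runs": report.n_runs,
    }


def run_all(
    manifest,
    config: RunConfig,
    output_dir,
    skip_failures: bool = False,
) -> dict:
    """Run the full analysis for every subject in the manifest.

    ``manifest`` is a manifest CSV path or a list of :class:`ManifestEntry`.
    Per-subject failures abort the run by default (a partial cohort biases
    the statistics); ``skip_failures=True`` drops failing subjects with a
    logged warning instead.  Returns the in-memory results dictionary; all
    artifacts (connectivity matrices, metrics table, OOB predictions, report
    and provenance JSON) are written under ``output_dir``.
    """
    entries = read_manifest(manifest) if not isinstance(manifest, list) else manifest
    out = Path(output_dir)
    (out / "connectivity").mkdir(parents=True, exist_ok=True)

    metric_rows = []
    kept: list[ManifestEntry] = []
    for entry in entries:
        logger.info("subject %s: ingest + preprocess", entry.subject_id)
        try:
            ts = preprocess_timeseries(read_timeseries(entry.timeseries_path), config)
            row_pair = {}
            for method in METHODS:
                cm = connectivity_matrix(ts, method, config.mi)
                write_connectivity(
                    cm, out / "connectivity" / f"{entry.subject_id}_{method}.tsv"
                )
                nm = subject_metrics(WeightedGraph.from_connectivity(cm))
                row_pair[method] = {
                    "subject_id": entry.subject_id,
                    "method": method,
                    **dict(zip(METRIC_NAMES, nm.as_array())),
                    "connected": nm.connected,
                }
        except Exception:
            if skip_failures:
                logger.warning("subject %s failed; skipping", entry.subject_id, exc_info=True)
                continue
            logger.error("subject %s failed; aborting (use skip_failures to override)", entry.subject_id)
            raise
        metric_rows.extend(row_pair.values())
        kept.append(entry)

    if len(kept) < 8:
        raise RuntimeError("fewer than 8 usable subjects; cannot fit the forest")

    metrics_df = pd.DataFrame(metric_rows)
    metrics_path = out / "metrics.csv"
    metrics_df.to_csv(metrics_path, index=False, float_format="%.12g")

    iq = np.array([e.iq for e in kept])
    subject_ids = tuple(e.subject_id for e in kept)
    reports = {}
    cohorts = {}
    for method in METHODS:
        sub = metrics_df[metrics_df["method"] == method].set_index("subject_id")
        feats = sub.loc[list(subject_ids), list(METRIC_NAMES)].to_numpy()
        cohorts[method] = CohortFeatures(
            subject_ids=subject_ids, features=feats, iq=iq, method=method
        )
        logger.info("fitting %d forest runs on %s metrics", config.n_runs, method)
        reports[method] = repeated_runs(
            cohorts[method],
            n_runs=config.n_runs,
            n_trees=config.n_trees,
            base_seed=config.base_seed,
        )

    preds = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "iq": iq,
            **{
                f"oob_prediction_{m}": reports[m].mean_oob_predictions
                for m in METHODS
            },
            **{f"abs_error_{m}": reports[m].abs_errors for m in METHODS},
        }
    )
    preds.to_csv(out / "oob_predictions.csv", index=False, float_format="%.12g")

    _, err_p = compare_absolute_errors(
        reports["pearson_abs"].abs_errors, reports["grid_mi"].abs_errors
    )
    metric_comparisons = {}
    spearman = {m: {} for m in METHODS}
    for name in METRIC_NAMES:
        a = cohorts["pearson_abs"].features[:, METRIC_NAMES.index(name)]
        b = cohorts["grid_mi"].features[:, METRIC_NAMES.index(name)]
        p_adj, r, ci = compare_graph_metrics(a, b)
        metric_comparisons[name] = {
            "wilcoxon_p_adjusted": p_adj,
            "pearson_r": r,
            "r_ci": list(ci),
            "pearson_graph_mean": float(a.mean()),
            "pearson_graph_sd": float(a.std(ddof=1)),
            "mi_graph_mean": float(b.mean()),
            "mi_graph_sd": float(b.std(ddof=1)),
        }
        for m in METHODS:
            rho, p = spearman_bonferroni(
                cohorts[m].features[:, METRIC_NAMES.index(name)], iq
            )
            spearman[m][name] = {"rho": rho, "p_adjusted": p}

    results = {
        "n_subjects": len(kept),
        "reports": {m: _report_to_dict(reports[m]) for m in METHODS},
        "abs_error_wilcoxon_p": err_p,
        "metric_comparisons": metric_comparisons,
        "spearman_vs_iq": spearman,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    provenance = {
        "package": "miconn",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "base_seed": config.base_seed,
        "n_subjects": len(kept),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    results["_reports"] = reports  # in-memory objects for library callers
    return results
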