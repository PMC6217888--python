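"""Synthetic BOLD-like cohorts with controlled linear/nonlinear coupling.

The study data this package targets (pediatric resting-state fMRI with
neuropsychological IQ) are protected health information, so every downstream
stage is exercised on synthetic cohorts instead.  The generator plants a
modular dependence structure:

- each module m has a latent signal z_m(t) of iid Gaussian innovations,
  optionally smoothed with a causal gamma-shaped kernel (shape 6, scale 0.9
  time steps) to mimic hemodynamic low-pass filtering;
- each node couples to its module latent either linearly or through a
  nonlinear transform (square, absolute value, or one-step lag), the share of
  nonlinear nodes set by ``nonlinear_fraction``.  Square and absolute value
  are uncorrelated with the latent itself, so Pearson edges between a linear
  and a nonlinear node of the same module are near zero while their mutual
  dependence remains strong — the regime where an MI edge and a correlation
  edge disagree;
- a global latent shared by all nodes produces weak between-module coupling;
- white Gaussian noise is added per node.

Each subject carries a latent ``true_integration`` multiplier on the
within-module coupling, drawn Uniform(0.5, 1.5), and an IQ that is a noisy
affine function of it (clipped to the plausible Wechsler range [40, 160]).
All randomness descends from ``CohortSpec.seed``; identical specs produce
bit-identical cohorts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import gamma as gamma_dist

from .connectivity import TimeSeriesMatrix
from .graph_metrics import WeightedGraph

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "CohortSpecError",
    "generate_subject",
    "generate_cohort",
    "planted_partition_graph",
    "write_cohort",
]

NONLINEAR_TRANSFORMS = ("square", "abs", "lag")


class CohortSpecError(ValueError):
    """A cohort specification violates one of its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults emulate the target study's scale: 24 subjects, several tens of
    nodes, 295 retained time points, with a mixed linear/nonlinear coupling
    structure and an IQ spread comparable to the clinical cohort (52-129).
    """

    n_subjects: int = 24
    n_nodes: int = 60
    n_timepoints: int = 295
    n_modules: int = 4
    within_coupling: float = 0.7
    between_coupling: float = 0.25
    nonlinear_fraction: float = 0.5
    noise_sd: float = 0.4
    iq_intercept: float = 30.0
    iq_slope: float = 60.0
    iq_noise_sd: float = 5.0
    seed: int = 0
    hemodynamic_smoothing: bool = True

    def __post_init__(self) -> None:
        def bad(field: str, why: str):
            return CohortSpecError(f"{field}: {why}")

        if self.n_subjects < 1:
            raise bad("n_subjects", "must be >= 1")
        if self.n_timepoints < 30:
            raise bad("n_timepoints", "must be >= 30")
        if self.n_modules < 1:
            raise bad("n_modules", "must be >= 1")
        if self.n_nodes < 2 * self.n_modules:
            raise bad("n_nodes", "must be >= 2 * n_modules")
        if not 0.0 <= self.between_coupling < self.within_coupling <= 1.0:
            raise bad(
                "between_coupling",
                "need 0 <= between_coupling < within_coupling <= 1",
            )
        if not 0.0 <= self.nonlinear_fraction <= 1.0:
            raise bad("nonlinear_fraction", "must lie in [0, 1]")
        if self.noise_sd < 0:
            raise bad("noise_sd", "must be >= 0")
        if self.iq_noise_sd < 0:
            raise bad("iq_noise_sd", "must be >= 0")


@dataclass
class SyntheticSubject:
    """One simulated subject: node time series plus the latent IQ driver."""

    subject_id: str
    timeseries: TimeSeriesMatrix
    true_integration: float
    iq: float


def _gamma_kernel(shape: float = 6.0, scale: float = 0.9, length: int = 16) -> np.ndarray:
    """Causal gamma-shaped smoothing kernel, unit L2 norm."""
    t = np.arange(length, dtype=np.float64)
    k = gamma_dist.pdf(t, a=shape, scale=scale)
    return k / np.linalg.norm(k)


def _smooth(z: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(z, kernel)[: z.size]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0.0:  # pragma: no cover - excluded by construction
        raise ValueError("degenerate latent signal")
    return (v - v.mean()) / sd


def module_assignments(spec: CohortSpec) -> np.ndarray:
    """Contiguous-block node -> module map (same for every subject)."""
    return np.repeat(
        np.arange(spec.n_modules),
        np.diff(np.linspace(0, spec.n_nodes, spec.n_modules + 1).astype(int)),
    )


def node_transforms(spec: CohortSpec) -> tuple[str, ...]:
    """Per-node coupling transform, hash-derived from the cohort seed.

    A ``nonlinear_fraction`` share of the nodes of each module couples
    nonlinearly; the transform is drawn from a fixed menu.  Cohort-level and
    deterministic, so every subject shares the same coupling structure.
    """
    rng = np.random.default_rng([int(spec.seed), 0x5EED])
    modules = module_assignments(spec)
    transforms = ["linear"] * spec.n_nodes
    for m in range(spec.n_modules):
        nodes = np.flatnonzero(modules == m)
        n_nl = int(round(spec.nonlinear_fraction * nodes.size))
        chosen = rng.choice(nodes, size=n_nl, replace=False)
        for i in chosen:
            transforms[int(i)] = str(rng.choice(NONLINEAR_TRANSFORMS))
    return tuple(transforms)


def _apply_transform(z: np.ndarray, transform: str) -> np.ndarray:
    if transform == "linear":
        return z
    if transform == "square":
        return _standardize(z**2)
    if transform == "abs":
        return _standardize(np.abs(z))
    if transform == "lag":
        return np.concatenate([z[:1], z[:-1]])
    raise ValueError(f"unknown transform {transform!r}")


def generate_subject(spec: CohortSpec, subject_index: int) -> SyntheticSubject:
    """Generate one subject's node x time matrix plus its latent IQ driver."""
    if not isinstance(spec, CohortSpec):
        spec = CohortSpec(**spec)
    if not 0 <= subject_index:
        raise ValueError("subject_index must be nonnegative")
    rng = np.random.default_rng([int(spec.seed), 0x0B1D, int(subject_index)])
    t = spec.n_timepoints
    kernel = _gamma_kernel() if spec.hemodynamic_smoothing else None

    def latent() -> np.ndarray:
        z = rng.standard_normal(t)
        if kernel is not None:
            z = _smooth(z, kernel)
        return _standardize(z)

    true_integration = float(rng.uniform(0.5, 1.5))
    z_modules = [latent() for _ in range(spec.n_modules)]
    z_global = latent()

    modules = module_assignments(spec)
    transforms = node_transforms(spec)
    c_within = spec.within_coupling * true_integration
    values = np.empty((spec.n_nodes, t))
    for i in range(spec.n_nodes):
        base = _apply_transform(z_modules[modules[i]], transforms[i])
        values[i] = (
            c_within * base
            + spec.between_coupling * z_global
            + spec.noise_sd * rng.standard_normal(t)
        )
    iq = spec.iq_intercept + spec.iq_slope * true_integration
    iq += float(rng.normal(0.0, spec.iq_noise_sd)) if spec.iq_noise_sd > 0 else 0.0
    iq = float(np.clip(iq, 40.0, 160.0))
    ts = TimeSeriesMatrix(values=values)
    if (ts.values.std(axis=1) == 0).any():  # pragma: no cover - noise_sd=0 edge
        raise CohortSpecError("noise_sd: produced a constant node series")
    return SyntheticSubject(
        subject_id=f"sub-{subject_index:03d}",
        timeseries=ts,
        true_integration=true_integration,
        iq=iq,
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate the full cohort, one subject per index."""
    if not isinstance(spec, CohortSpec):
        spec = CohortSpec(**spec)
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


def planted_partition_graph(
    n_nodes: int,
    n_modules: int,
    w_in: float,
    w_out: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> WeightedGraph:
    """Symmetric planted-partition weight matrix (metrics-module test fixture).

    Within-module weights sit near ``w_in`` and between-module weights near
    ``w_out`` (Gaussian jitter, then clipped to [0, 1]); the diagonal is zero.
    """
    if not 0.0 <= w_out < w_in <= 1.0:
        raise ValueError("need 0 <= w_out < w_in <= 1")
    if n_modules < 1 or n_nodes < n_modules:
        raise ValueError("need n_nodes >= n_modules >= 1")
    labels = np.repeat(
        np.arange(n_modules),
        np.diff(np.linspace(0, n_nodes, n_modules + 1).astype(int)),
    )
    w = np.where(labels[:, None] == labels[None, :], w_in, w_out).astype(np.float64)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        jit = rng.normal(0.0, jitter_sd, size=(n_nodes, n_nodes))
        w = w + np.triu(jit, 1) + np.triu(jit, 1).T
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(weights=w)


def write_cohort(subjects: list[SyntheticSubject], out_dir) -> Path:
    """Write per-subject TSV matrices plus a manifest CSV; returns the manifest path.

    The manifest has columns ``subject_id,path,iq`` and round-trips through
    the pipeline readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "path", "iq"])
        for subj in subjects:
            ts_path = out_dir / f"{subj.subject_id}_timeseries.tsv"
            with open(ts_path, "w") as tfh:
                for nid, row in zip(subj.timeseries.node_ids, subj.timeseries.values):
                    tfh.write(nid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
            writer.writerow([subj.subject_id, str(ts_path), f"{subj.iq:.17g}"])
    return manifest
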