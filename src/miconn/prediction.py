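"""Random-forest IQ prediction with out-of-bag evaluation, plus the paired
statistics used to compare Pearson- and MI-derived network metrics.

The forest is Breiman bagging over CART regression trees: each tree is grown
on a bootstrap sample of subjects (one candidate feature per split, unlimited
depth); a subject's out-of-bag (OOB) prediction is the mean over the trees
whose bootstrap excluded it.  Accuracy is summarised as the fractional
variation explained, FVE = 1 - MSE_oob / Var(y) (population variance), and
the mean absolute error.  Repeating the forest under shifted seeds gives a
percentile confidence interval for FVE.  Variable importance is OOB
permutation importance: the mean per-tree increase in OOB MSE when one
feature is shuffled among that tree's OOB subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .graph_metrics import METRIC_NAMES

__all__ = [
    "CohortFeatures",
    "OobRun",
    "PredictionReport",
    "fit_oob",
    "fractional_variation_explained",
    "repeated_runs",
    "variable_importance",
    "compare_absolute_errors",
    "spearman_bonferroni",
    "compare_graph_metrics",
    "fisher_r_ci",
]


@dataclass
class CohortFeatures:
    """Per-subject network metrics (columns in METRIC_NAMES order) and IQ."""

    subject_ids: tuple[str, ...]
    features: np.ndarray
    iq: np.ndarray
    method: str

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.iq, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != len(METRIC_NAMES):
            raise ValueError(f"features must be subjects x {len(METRIC_NAMES)}")
        if y.shape != (x.shape[0],):
            raise ValueError("iq must have one value per subject")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("features and iq must be finite (no missing values)")
        if x.shape[0] < 8:
            raise ValueError("need at least 8 subjects for a model fit")
        if y.var() == 0:
            raise ValueError("IQ variance must be > 0")
        self.features = x
        self.iq = y
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        if len(self.subject_ids) != x.shape[0]:
            raise ValueError("subject_ids length must match features")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]


@dataclass
class OobRun:
    """One forest fit: per-subject OOB predictions and its FVE / MAE."""

    run_seed: int
    oob_predictions: np.ndarray
    fve: float
    mae: float


@dataclass
class PredictionReport:
    """Repeated-run summary for one graph type."""

    method: str
    fve_mean: float
    fve_ci: tuple[float, float]
    mae_mean: float
    mae_sd: float
    importance: np.ndarray
    n_runs: int
    mean_oob_predictions: np.ndarray
    abs_errors: np.ndarray

    def __post_init__(self) -> None:
        lo, hi = self.fve_ci
        if not lo <= self.fve_mean <= hi:
            raise ValueError("fve_ci must bracket fve_mean")


def fractional_variation_explained(oob_predictions, iq) -> float:
    """FVE = 1 - MSE(pred, iq) / Var_pop(iq).  May be negative; always <= 1."""
    pred = np.asarray(oob_predictions, dtype=np.float64)
    y = np.asarray(iq, dtype=np.float64)
    if pred.shape != y.shape:
        raise ValueError("prediction and IQ vectors must have equal length")
    var = y.var()  # population (n-denominator) variance
    if var == 0:
        raise ValueError("IQ variance must be > 0")
    mse = float(np.mean((pred - y) ** 2))
    return 1.0 - mse / float(var)


def _bagged_trees(x: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator):
    """Yield (tree, bootstrap_indices, oob_indices) for one forest."""
    n = y.size
    idx = np.arange(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(idx, boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=1, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(x[boot], y[boot])
        yield tree, boot, oob


def fit_oob(cohort: CohortFeatures, n_trees: int = 500, run_seed: int = 0) -> OobRun:
    """Fit one random forest and evaluate it out of bag.

    Deterministic given ``run_seed``.  Raises if any subject is never out of
    bag (use more trees).
    """
    x, y = cohort.features, cohort.iq
    n = cohort.n_subjects
    rng = np.random.default_rng(int(run_seed))
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=np.int64)
    for tree, _, oob in _bagged_trees(x, y, n_trees, rng):
        if oob.size == 0:
            continue
        pred_sum[oob] += tree.predict(x[oob])
        pred_cnt[oob] += 1
    if (pred_cnt == 0).any():
        missing = [cohort.subject_ids[i] for i in np.flatnonzero(pred_cnt == 0)]
        raise RuntimeError(
            f"subjects never out of bag: {missing}; increase n_trees (>= 100 recommended)"
        )
    oob_pred = pred_sum / pred_cnt
    return OobRun(
        run_seed=int(run_seed),
        oob_predictions=oob_pred,
        fve=fractional_variation_explained(oob_pred, y),
        mae=float(np.mean(np.abs(oob_pred - y))),
    )


def variable_importance(
    cohort: CohortFeatures, n_trees: int = 500, run_seed: int = 0
) -> np.ndarray:
    """OOB permutation importance per metric (METRIC_NAMES order).

    For each tree, each feature is shuffled among that tree's OOB subjects
    and the increase in OOB MSE over the unshuffled baseline is recorded;
    importances are means over trees.  Near zero (either sign) for features
    carrying no signal.
    """
    x, y = cohort.features, cohort.iq
    fit_ss, perm_ss = np.random.SeedSequence(int(run_seed)).spawn(2)
    rng = np.random.default_rng(fit_ss)
    perm_rng = np.random.default_rng(perm_ss)
    n_feat = x.shape[1]
    inc = np.zeros(n_feat)
    used = 0
    for tree, _, oob in _bagged_trees(x, y, n_trees, rng):
        if oob.size < 2:
            continue
        x_oob, y_oob = x[oob], y[oob]
        base = float(np.mean((tree.predict(x_oob) - y_oob) ** 2))
        for f in range(n_feat):
            x_perm = x_oob.copy()
            x_perm[:, f] = perm_rng.permutation(x_perm[:, f])
            inc[f] += float(np.mean((tree.predict(x_perm) - y_oob) ** 2)) - base
        used += 1
    if used == 0:
        raise RuntimeError("no tree had at least 2 OOB subjects; increase n_trees")
    return inc / used


def repeated_runs(
    cohort: CohortFeatures,
    n_runs: int = 500,
    n_trees: int = 500,
    base_seed: int = 0,
) -> PredictionReport:
    """Repeat the forest fit under seeds base_seed..base_seed+n_runs-1.

    The FVE confidence interval is the 2.5th/97.5th percentile of per-run
    FVE; MAE mean +/- SD is computed from the per-subject absolute errors of
    the across-run mean OOB prediction (one paired error per subject).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = [fit_oob(cohort, n_trees=n_trees, run_seed=base_seed + i) for i in range(n_runs)]
    fves = np.array([r.fve for r in runs])
    preds = np.vstack([r.oob_predictions for r in runs])
    mean_pred = preds.mean(axis=0)
    abs_err = np.abs(mean_pred - cohort.iq)
    lo, hi = np.percentile(fves, [2.5, 97.5])
    return PredictionReport(
        method=cohort.method,
        fve_mean=float(fves.mean()),
        fve_ci=(float(lo), float(hi)),
        mae_mean=float(abs_err.mean()),
        mae_sd=float(abs_err.std(ddof=1)) if abs_err.size > 1 else 0.0,
        importance=variable_importance(cohort, n_trees=n_trees, run_seed=base_seed),
        n_runs=n_runs,
        mean_oob_predictions=mean_pred,
        abs_errors=abs_err,
    )


def _paired_wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired differences.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 untied nonzero differences, otherwise the normal approximation.
    """
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=3)
        return 0.0, 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_absolute_errors(errors_a, errors_b) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on per-subject absolute errors."""
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 6:
        raise ValueError("need paired error vectors of equal length >= 6")
    return _paired_wilcoxon(a - b)


def spearman_bonferroni(metric_values, iq, n_tests: int = 4) -> tuple[float, float]:
    """Spearman rho of one metric with IQ, Bonferroni-adjusted p-value."""
    x = np.asarray(metric_values, dtype=np.float64)
    y = np.asarray(iq, dtype=np.float64)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need paired vectors of equal length >= 5")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(min(1.0, n_tests * p))


def fisher_r_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n <= 3:
        raise ValueError("need n > 3 for a Fisher interval")
    rr = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.arctanh(rr)
    hw = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - hw)), float(np.tanh(z + hw))


def compare_graph_metrics(
    metrics_pearson, metrics_mi, n_tests: int = 4
) -> tuple[float, float, tuple[float, float]]:
    """Compare one metric across graph types, paired over subjects.

    Returns the Bonferroni-adjusted two-sided Wilcoxon p-value, the Pearson
    correlation between the two per-subject metric vectors, and its Fisher-z
    95% CI.
    """
    a = np.asarray(metrics_pearson, dtype=np.float64)
    b = np.asarray(metrics_mi, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 6:
        raise ValueError("need paired metric vectors of equal length >= 6")
    _, p = _paired_wilcoxon(a - b)
    p_adj = float(min(1.0, n_tests * p))
    if a.var() == 0 or b.var() == 0:
        raise ValueError("constant metric vector: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    return p_adj, r, fisher_r_ci(r, a.size)
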