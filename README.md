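# miconn

Functional connectivity between brain regions is usually measured as the
Pearson correlation of their resting-state BOLD time series, which assumes the
physiologically relevant coupling is linear and zero-lag. `miconn` implements
an alternative, a **grid-maximised mutual information** edge estimator, and
everything needed to ask whether it captures network architecture that
correlation misses: weighted graph metrics computed on both kinds of
connectivity matrix, and an out-of-bag random-forest prediction of subject IQ
from those metrics. Because the clinical data this methodology targets are
protected health information, the package ships a synthetic-cohort generator
with controlled linear/nonlinear coupling so the whole pipeline is testable
and reproducible end to end.

## The method

**Edges.** For node time series X, Y, either `|r|` (absolute Pearson
correlation) or

&nbsp;&nbsp;&nbsp;&nbsp;MI(X, Y) = Σₓ Σ_y p(x, y) ln [ p(x, y) / (p(x) p(y)) ]

estimated by frequency counts on a 3×3 discretisation of the joint sample.
Per axis, the outer bin boundaries are the series min and max and the middle
two sit at mean ± m·SD for multiples m ∈ {0.25, 0.5, 0.75, 1.0, 1.25} — 25
candidate boundary pairs per axis and 125 candidate grids per node pair (the
lower multiple is shared across axes). The edge weight is the **maximum MI
over the candidate grids**, a fixed-resolution relative of the maximal
information coefficient (maximising over all resolutions is infeasible for
the ~3×10⁵ node pairs of a whole-brain graph). MI is in nats, so jointly
Gaussian pairs fall on the reference curve −½ ln(1 − r²).

**Graph metrics.** Each weighted, undirected connectivity matrix is summarised
by four Brain Connectivity Toolbox–convention metrics: weighted clustering
coefficient (Onnela geometric-mean form, max-normalised), Newman modularity Q
(deterministic leading-eigenvector splitting with Kernighan–Lin refinement),
characteristic path length and global efficiency (Dijkstra on 1/w edge
lengths).

**Prediction.** A random forest (bagged CART trees, one candidate feature per
split) predicts IQ from the four metrics only; each subject is scored
out-of-bag. Accuracy is the fractional variation explained,
FVE = 1 − MSE_oob/Var(IQ), with a percentile CI over repeated runs, plus the
mean absolute error. Feature importance is out-of-bag permutation importance;
graph types are compared with paired Wilcoxon signed-rank tests (exact for
n ≤ 25), Pearson correlations with Fisher-z CIs, and Spearman correlations
with Bonferroni adjustment.

## Worked example

```python
import numpy as np
from miconn import (
    CohortSpec, CohortFeatures, WeightedGraph, connectivity_matrix,
    generate_cohort, subject_metrics, repeated_runs,
)

spec = CohortSpec(n_subjects=24, n_nodes=60, nonlinear_fraction=0.6, seed=11)
cohort = generate_cohort(spec)
iq = np.array([s.iq for s in cohort])

for method in ("pearson_abs", "grid_mi"):
    feats = np.vstack([
        subject_metrics(
            WeightedGraph.from_connectivity(connectivity_matrix(s.timeseries, method))
        ).as_array()
        for s in cohort
    ])
    features = CohortFeatures(
        subject_ids=tuple(s.subject_id for s in cohort),
        features=feats, iq=iq, method=method,
    )
    report = repeated_runs(features, n_runs=50, n_trees=500, base_seed=0)
    print(
        f"{method:11s}  FVE {report.fve_mean:.2f} "
        f"(95% CI {report.fve_ci[0]:.2f}-{report.fve_ci[1]:.2f})  "
        f"MAE {report.mae_mean:.1f} +/- {report.mae_sd:.1f} IQ points"
    )
```

prints (~2 minutes on one core):

```
pearson_abs  FVE 0.63 (95% CI 0.61-0.64)  MAE 9.7 +/- 5.1 IQ points
grid_mi      FVE 0.86 (95% CI 0.85-0.87)  MAE 5.5 +/- 4.0 IQ points
```

On this cohort — where 60% of each module's nodes couple to the module signal
through a nonlinear transform that correlation cannot see — graph metrics from
MI-defined connectivity explain substantially more out-of-bag IQ variance and
halve the prediction error relative to Pearson-defined connectivity. Subject
by subject, the MI graphs also show lower clustering and global efficiency and
longer path lengths than the corresponding Pearson graphs, because
grid-estimated MI places edge weights in a lower range than `|r|`.

A command-line interface mirrors the pipeline stages:

```bash
miconn simulate --n-subjects 24 --n-nodes 60 --seed 11 --output-dir cohort/
miconn run-all cohort/manifest.csv --n-runs 200 --seed 1 --output-dir results/
```

`run-all` writes per-subject connectivity matrices, a metrics table CSV,
out-of-bag predictions, a JSON report and a provenance record (config hash,
seeds, versions); reruns with the same inputs and seeds are byte-identical.

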