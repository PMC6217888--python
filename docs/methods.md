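# Methods notes

This note records the modelling choices behind `miconn`: the estimators, the
synthetic-cohort generative model, numerical conventions, and what the test
suite does and does not establish about real data.

## Grid-maximised mutual information

For a pair of node time series the MI edge is the plug-in (frequency-count)
mutual information on a 3×3 discretisation, maximised over a family of
candidate grids. Per axis the four bin boundaries are

- outer: the series minimum and maximum;
- middle: mean − m_low·SD and mean + m_up·SD, with the multiples drawn from
  {0.25, 0.5, 0.75, 1.0, 1.25} (configurable via `MiConfig`).

With five multiples there are 25 candidate middle-boundary pairs per axis.
The default enumeration shares the lower multiple between the two axes and
frees the two upper multiples, giving exactly 5³ = 125 candidate grids per
pair, a family that is closed under swapping the axes (so the estimator is
symmetric). The fully independent 5⁴ enumeration is available as
`enumeration_mode="full"`. Candidate grids whose boundaries are not strictly
ascending (a middle boundary landing at or outside the data range) are dropped
from the maximisation; a pair for which every grid degenerates raises an
error rather than silently contributing 0.

Conventions, each chosen to make every observation count exactly once and the
estimate reproducible:

- sample SD (n−1 denominator);
- bin membership [b₀,b₁), [b₁,b₂), [b₂,b₃] — the last bin is right-closed so
  the maximum is counted;
- natural logarithm, so the estimate is in nats, bounded by ln 3 ≈ 1.0986,
  and jointly Gaussian pairs track the closed form −½ ln(1−r²);
- 0·ln 0 ≡ 0; tiny negative totals from floating-point cancellation are
  clamped to 0;
- constant series are an error, never MI = 0: upstream data should not
  contain them, and silence would mask bugs.

The maximisation is a fixed-resolution relative of the maximal information
coefficient. Maximising over resolutions as MIC does is computationally out
of reach for the ~1,770–300,000 pairs of a whole-brain graph, so the
resolution is pinned at 3×3; the candidate multiples are the one genuinely
free family in the estimator and are exposed in `MiConfig`.

Being a maximum over 125 correlated plug-in estimates, the edge weight is
biased upward at independence. At the study series length (295 samples) the
null mean is ≈ 0.02 nats (the acceptance script recomputes it), an order of
magnitude below typical coupled-pair values.

## Graph metrics

All four metrics follow Brain Connectivity Toolbox conventions for weighted
undirected matrices:

- **Clustering** — Onnela geometric-mean triangle form on weights normalised
  by the graph maximum; nodes of degree < 2 contribute 0. Invariant to
  uniform rescaling of the weights.
- **Modularity** — Newman Q maximised by recursive leading-eigenvector
  bisection with Kernighan–Lin single-node refinement, resolution γ = 1. The
  algorithm is deterministic (no stochastic Louvain), so identical inputs give
  identical partitions; the returned Q is always the direct evaluation of the
  Q formula on the returned partition. Heuristic optimality is not
  guaranteed; property tests compare against brute-force partition search on
  small graphs and warn on (rare) gaps.
- **Path length / efficiency** — Dijkstra shortest paths on edge lengths 1/w
  (absent edge → infinite length). Path length is the mean over *reachable*
  ordered pairs, with a `connected` flag exposed instead of returning
  infinity: fully weighted connectivity matrices are almost always connected,
  and silent infinities would poison the downstream statistics. Efficiency is
  the standard mean of inverse distances (1/∞ ≡ 0). A common informal
  description of efficiency as "the inverse of the mean path length" differs
  from this definition; the standard toolbox form is implemented.

## Random forest and statistics

- Bagged CART regression trees (scikit-learn base learner), defaults: 500
  trees, one candidate feature per split (⌊4/3⌋), unlimited depth, min leaf 1.
  Bagging and out-of-bag bookkeeping are implemented in the package so that
  each subject's OOB prediction is exactly the mean over trees whose bootstrap
  excluded it, and so the whole fit is reproducible from one integer seed.
- FVE = 1 − MSE_oob / Var_pop(y) with the population (n-denominator)
  variance — the standard forest "% variance explained". It is 0 for the
  mean predictor and can be negative.
- Repeated runs use seeds base_seed…base_seed+n_runs−1; the FVE CI is the
  2.5th/97.5th percentile across runs. The MAE mean ± SD is computed from the
  per-subject absolute errors of the across-run mean OOB prediction — one
  paired error per subject, which is also what the paired Wilcoxon comparison
  between graph types consumes.
- Variable importance is OOB permutation importance: per tree, each feature
  is shuffled among that tree's OOB subjects and the increase in OOB MSE over
  the unshuffled baseline is averaged over trees.
- Wilcoxon signed-rank comparisons are two-sided, zero differences dropped,
  exact null for ≤ 25 nonzero differences, normal approximation otherwise.
  Spearman correlations with IQ are Bonferroni-adjusted (×4, capped at 1);
  between-graph-type Pearson correlations carry Fisher-z 95% CIs.

## The synthetic cohort

No generative model of the clinical data exists, so the generator is a
designed stand-in, built to reproduce the *structure* of the problem rather
than any patient-level numbers:

- **Latents.** Each of the `n_modules` modules has a latent signal of iid
  Gaussian innovations convolved with a causal gamma-shaped kernel (shape 6,
  scale 0.9 time steps, unit L2 norm) — a low-pass hemodynamic-like smoothing,
  not a full HRF model — then standardised. A global latent shared by all
  nodes produces between-module coupling.
- **Nodes.** Node i in module m is
  `within_coupling·true_integration · g_i(z_m) + between_coupling · z₀ + noise_sd · ε`,
  where g_i is the identity for linear nodes and a standardised square,
  absolute value, or one-step lag for nonlinear nodes. Square and absolute
  value are uncorrelated with the latent itself (symmetric z), so
  linear×nonlinear pairs within a module have |r| ≈ 0 but strong mutual
  dependence — the exact regime where the two edge definitions disagree. The
  transform assignment is drawn once per cohort from the seed;
  `nonlinear_fraction` is applied per node (a pair-level assignment cannot
  exceed a 50% nonlinear-pair share, since 2p(1−p) ≤ ½).
- **Subjects.** `true_integration ~ Uniform(0.5, 1.5)` multiplies the
  within-module coupling — one interpretable knob that moves all four graph
  metrics — and IQ = 30 + 60·true_integration + N(0, 5), clipped to
  [40, 160], giving a cohort IQ spread comparable to a clinical Wechsler
  range (roughly 50–130).
- **Scale and SNR defaults.** 24 subjects, 60 nodes, 295 retained time
  points; `within_coupling = 0.7`, `between_coupling = 0.25`,
  `noise_sd = 0.4`. The SNR values are calibrated so the edge-strength
  distribution resembles resting-state data: strongest within-module pairs
  reach |r| ≈ 0.7–0.85, between-module pairs sit near |r| ≈ 0.1. This regime
  matters: because −½ ln(1−r²) is convex with f(0) = 0, strong maximum edges
  push MI weights into a relatively lower range than |r| after
  max-normalisation, which is what produces the observed lower clustering and
  efficiency and longer path length of MI graphs. In a much weaker-coupled
  regime (max |r| ≲ 0.6) the estimator's null bias floor becomes comparable,
  relative to the maximum edge, for both methods, and those directional
  differences wash out.

What the generator does **not** emulate: voxel-level imaging, motion and
physiological artifacts, spatial autocorrelation between neighbouring
parcels, non-stationarity, and realistic 1/f BOLD spectra. Passing tests
therefore demonstrate that the pipeline recovers planted structure of the
kind hypothesised for real data — not that real patient cohorts would yield
any particular effect size. Published patient-cohort effect sizes require
the restricted clinical data and are not reproduced here.

## Pipeline conventions

- Input is plain delimited text (nodes × time, optional leading node-id
  column) plus a manifest CSV (`subject_id,path,iq`); image-level processing
  is out of scope and node series are the package's true boundary.
- Preprocessing drops the first 5 volumes (magnetisation equilibration) and
  applies an ideal frequency-domain high-pass at 0.01 Hz (100 s period; TR
  2 s by default), removing components strictly below the cutoff and
  restoring each node's mean. An ideal filter is used instead of a
  Gaussian-weighted running-line detrend because it is simple, exactly
  characterised, and testable on constructed sinusoids.
- Per-subject failures abort the run by default — at n ≈ 24, silently losing
  subjects biases every downstream statistic — with an explicit
  `skip_failures` override.
- All randomness flows from seeds recorded in the provenance record;
  identical manifest + config + seeds give byte-identical CSV/JSON artifacts.

## Problem sizes used by tests and the acceptance script

Unit tests run on small constructed graphs and short series with independent
oracles (brute-force grid re-binning, Floyd–Warshall, exhaustive partition
search). The cohort-level checks and the acceptance script use 24 subjects ×
60 nodes × 295 retained time points with `nonlinear_fraction = 0.6`, 50
paired forest runs in the tests and 200 repeated runs per graph type in the
acceptance script — sizes chosen so the full analysis, including ~1,770
125-grid MI maximisations per subject, completes in minutes on one core while
keeping Monte-Carlo error well below the effects being asserted.

## Known limitations

- The five SD multiples and the 125-grid combinatorial scheme are one
  defensible realisation of a coarsely specified estimator family; both are
  configurable, and conclusions could in principle be sensitive to them.
- The spectral modularity heuristic can fall short of the global optimum on
  adversarial small graphs (tests warn rather than fail on such gaps).
- OOB permutation importance is one standard reading of "negating a variable
  during bagging"; alternatives (e.g. conditional importance) are not
  implemented.
- The generator's IQ link is affine in a single latent; real cognition–network
  relationships are surely higher-dimensional.
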