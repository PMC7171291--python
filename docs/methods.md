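# Methods

`restmodes` implements a dynamic functional-connectivity analysis chain:
ROI-level BOLD-like time series are windowed into short spans, each
window's signed connectivity is decomposed into communities, the window
partitions are classified against group task-mode templates by
chance-corrected mutual information, and the resulting per-subject
indices (task-state expression, state sequences, stable-core similarity)
feed reliability and brain-behavior analyses. Because the datasets this
kind of analysis targets are access-restricted, the package ships a
synthetic-cohort generator with fully known ground truth; every claim
the test suite makes is a claim about recovery of planted structure.

## Time-series preparation

Volumes are 0-based and windows half-open `[start, end)` everywhere.

**Confound regression** projects each ROI's series onto the complement
of `[intercept, linear trend, confounds]` by least squares; residuals
are orthogonal to every regressor. Rank deficiency is detected by
pivoted QR and reported with the offending column names.

**Band-pass filtering** is a linear detrend followed by a zero-phase
frequency-domain mask keeping `f_lo < f < f_hi` (defaults 0.008–0.09 Hz).
The contract tests pin pass/stop behavior (≥ 90% in-band retention,
≤ 10% stop-band leakage), not a particular filter realization. Optional
median-filter despiking exists but is off by default.

**Task regressors** convolve a block boxcar with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s; `nilearn`'s `spm_hrf`) on a
16× oversampled grid; the second column is the first finite difference
of the first.

**Sliding windows** are planned per run (windows never mix runs, hence
never mix phase-encoding directions): starts at `0, hop, 2·hop, …` while
the window fits. The two reference geometries are 4 runs × 1200 volumes
at TR 0.72 s with window 41 and hop 3 (1548 windows, 1544 possible
within-run switches) and one 180-volume run at TR 2 s with window 15 and
hop 1 (166 windows, 165 switches).

**Window connectivity** is a weighted Pearson correlation with symmetric
Hann weights normalized to sum 1 (uniform weights reduce it to ordinary
Pearson), Fisher-z transformed with `r` clipped at |r| = 0.999999 so
degenerate windows stay finite; diagonals are zeroed. ROIs with zero
weighted variance (relative tolerance 1e-12) get zero rows with a
warning. Static (full-run) connectivity standardizes each run before
concatenation so run-level offset/scale differences do not leak into the
correlations.

## Community detection

The objective is signed modularity with a premium on positive weights:
with `w±` the positive/negative parts, `s±` strengths, `v±` total
weights and `e±_ij = s±_i s±_j / v±`,

```
Q = (1/v+) Σ (w+ − γ e+) δ(ci,cj) − (1/(v+ + v−)) Σ (w− − γ e−) δ(ci,cj)
```

(the symmetric variant that divides the negative term by `v−` is
available behind `variant="negative_sym"`). Louvain is implemented as a
generalized two-phase optimizer on the modularity matrix
`B = (w+ − γe+)/v+ − (w− − γe−)/(v+ + v−)`: greedy seeded node sweeps
with first-best tie-breaking, then block aggregation of `B`, iterated to
a fixed point. Because moves are strictly improving from a singleton
start, the returned Q is never below the all-singletons Q. On random
structured signed graphs with n ≤ 8, single runs reach the exhaustive-
search optimum on ≥ 95% of instances (checked against enumeration of all
set partitions).

One caveat worth stating: adding positive within-community weight
increases Q only when the null model is held fixed (gain `2Δw/v+`). If
the null terms are recomputed from the modified graph, the added weight
also inflates `v+` and can *dilute* an already high Q; monotonicity in
that stronger form is false and is not asserted.

**Consensus.** Ensembles (default 100 restarts per resolution
γ ∈ {0.95, 1.00, 1.05}, processed independently and never pooled across
γ) are reduced by the agreement-matrix scheme: threshold the
co-assignment fraction at τ (default 0, i.e. keep any positive
agreement), re-cluster the thresholded matrix `reps` times with Louvain
at γ = 1, and iterate until all runs coincide. An all-zero thresholded
agreement returns singletons with a warning; non-convergence within
`max_iter` raises an error carrying the last agreement matrix for
inspection. The γ used on the agreement matrix is a package choice
(γ = 1): the consensus stage has no externally specified resolution.

## State dynamics

**AMI.** Partition similarity is the adjusted mutual information with
exact expected MI under the permutation (hypergeometric) model and
max-entropy normalization, `AMI = (I − E[I]) / (max(H_U, H_V) − E[I])`.
Two degenerate conventions: both partitions trivial → 1; exactly one
trivial → 0. The implementation agrees with a 50,000-permutation
Monte-Carlo estimate of E[I] to < 0.01 and with an independent
library implementation to 1e-10.

**Classification** labels each rest window with the argmax-AMI task
template; exact ties fall to the earlier mode in the canonical order
(perceptual, semantic, math, motor) and are flagged. Ordered sequence
counts consider consecutive windows *within* a run only; same-label
pairs are not switches, so `Σ counts ≤ Σ_runs (windows − 1)`.

**Stable core.** A subject's rest core is the consensus over all their
window partitions; its AMI profile against the task templates gives the
four similarity indices. Homologous indices are arithmetic-averaged
across the three resolution values.

**Leave-one-subject-out validation** rebuilds group templates from all
remaining subjects (block consensus per subject, then group consensus)
and classifies the left-out subject's block partitions; it reports
accuracy, per-mode precision averaged over predicted modes (PPV), and
the full confusion table.

## Reliability

ICC(2,1) — two-way random effects, absolute agreement, single measure —
is computed directly from the ANOVA mean squares:
`(MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))`. Column offsets
penalize the estimate (absolute agreement, not consistency); negative
estimates are reported as-is; an all-equal table is an error. Estimates
≥ 0.40 are flagged "fair to good". A motion residualizer (values on
intercept + per-subject mean displacement) supports the confound checks.

## Brain-behavior inference

**CCA** standardizes both sets and takes the SVD of
`Sxx^{-1/2} Sxy Syy^{-1/2}`; singular values are the canonical
correlations, weights are back-transformed singular vectors, loadings
are raw variable-variate Pearson correlations. Each mode's sign is
anchored so the first behavioral variable's weight is non-negative —
note this anchor is arbitrary with respect to any *other* behavioral
variable, so downstream sign interpretations must be made relative to
the weight of the variable of interest.

**Cross-validation** fits discovery CCAs on k−1 folds (default: 10
near-equal random folds; explicit fold sizes supported), standardizes
test subjects with training parameters, projects with training weights,
and pools predictions. Fold models are sign-aligned to a full-sample
reference by a joint (brain, behavior) flip, which leaves each model
equivalent but makes pooling orientation-consistent.

**Permutation inference for the pooled r.** Fold models share ~(k−2)/k
of their training subjects, so fold-wise test correlations are
positively dependent; permuting only the pooled variates therefore
understates the null variance badly (measured rejection ≈ 0.25 at
nominal 0.05, with or without sign alignment). `cca_crossval` instead
permutes the behavior table's subject rows and re-runs the entire
cross-validation per permutation, which is exact under subject
exchangeability; a lean numerical path (verified to reproduce the
model-building path exactly on the identity permutation) keeps 499
permutations at n = 300 near one second. Measured type-I error is ≈ 0.05
and power at a planted canonical correlation of 0.5 (n = 300) is
essentially 1, with pooled r within 0.5 ± 0.15 (cross-validation shrinks
r slightly below the planted value). Plain correlation and partial
correlation tests (`perm_test_correlation`, `partial_corr_perm`) permute
one vector directly — valid there because no fold structure exists — 
with the `(1 + #exceedances)/(n_perm + 1)` two-sided rule.

**Bootstrap screening** case-resamples the regression of an outcome on
standardized predictors (multinomial weights, batched normal equations),
with BCa intervals by default (bias correction from the bootstrap CDF at
the point estimate; acceleration from jackknife skewness) and percentile
intervals behind a flag. Rank-deficient resamples are redrawn and
counted. A predictor is "reliable" when its CI excludes zero. Measured
coverage at n = 200 with 500 resamples is within [0.90, 0.99].

**Transfer projection** standardizes a new cohort's features with their
own statistics, projects with the discovery brain weights after zeroing
selected entries, and residualizes the score on the zeroed variables
plus any confounds — the zeroed variables are covaried out rather than
contributing. `residualize_variate` uses (intercept + confounds) only;
the scan-time linear trend used in run-level confound regression has no
analogue over a subject index.

## Synthetic cohorts

The generator emulates a multi-subject task/rest study at ROI level; it
is deliberately minimal and its defaults are the package's study
conditions:

- **Templates**: one balanced partition per mode over `n_rois = 60` ROIs
  (K = 4 communities), with an `overlap` fraction (default 0.5) of ROIs
  shared across modes; the non-shared labels are reshuffled per mode so
  every template stays balanced. `overlap = 1` makes templates
  identical; `overlap = 0` makes them independent (pairwise AMI within
  the Monte-Carlo null band). With unequal K per mode, strict identity
  at `overlap = 1` is impossible; templates are then aligned through a
  shared random ROI ordering.
- **Signal**: `x(t,i) = √ρ g(t, c_i) + √(1−ρ) ε(t,i)` with independent
  standard Gaussian community factors and noise, so the within-community
  correlation is exactly ρ (default 0.6) and between-community
  correlation 0, all expectations closed-form. An optional AR(1)
  coefficient adds autocorrelation at unit marginal variance; it is 0 by
  default.
- **Rest dynamics**: each rest run is a Markov dwell sequence (dwell
  length = one window, 12 dwells by default at TR 2 s, window 15,
  hop 15) with subject-specific mode preferences drawn from a
  Dirichlet(α = 1) and a log-normal subject-specific boost on the
  perceptual→semantic transition. α = 1 matters: with strongly
  concentrated preferences (α ≳ 2) every subject's stable core collapses
  to the same cross-mode intersection partition and the similarity
  indices lose all between-subject variance; at α = 1 the qualitative
  association "more windows in a mode → higher core-template similarity"
  emerges with positive sign, as it should. True window labels follow
  the majority of each window's volumes (ties to the earlier dwell), and
  the true transition counts are tallied from those labels.
- **Behavior**: the planted neural composite is
  `z(−z(n_PS) + z(sim_math))` — fewer perceptual→semantic sequences plus
  greater rest-math-architecture similarity — where `sim_math` is the
  math dwell-fraction z-score plus N(0, 0.5²) measurement noise (the
  noisy similarity proxies also prevent the four dwell fractions, which
  sum to one, from making the feature table singular). The `visual_em`
  column equals `β·f + √(1−β²)·noise`, re-standardized; `age` and
  `verbal_em` are independent standard normals, giving clean nulls for
  specificity checks. `β = 1` reproduces the composite exactly; `β = 0`
  severs the link.

What the generator does *not* emulate: hemodynamics, realistic fMRI
noise spectra (1/f, physiological cycles), motion artifacts, spatial
structure, or non-stationary community strength. Passing tests
demonstrate that the estimators recover the structure this model plants
at the stated coupling and sample sizes — not that real acquisitions
satisfy the model.

## Pipeline scale and numerical choices

The end-to-end pipeline defaults are desk-scale: 20 subjects, 60 ROIs,
24 Louvain restarts / 24 consensus reps for task templates and 10/10 for
the (much more numerous) per-window ensembles, 5 CV folds, 9999
permutations. The study-scale settings (100 restarts, 100 reps, 3
resolutions, 10 folds, 100,000 permutations) are plain configuration
values. Calibration experiments (type-I error, bootstrap coverage) and
the CCA recovery runs operate on ground-truth-derived feature tables at
n = 300 — the planted link is defined at the feature level, and window-
level consensus for hundreds of subjects adds nothing to those checks.

All randomness flows from one seed through spawned
`numpy.random.SeedSequence` streams; reports are JSON with sorted keys
and no timestamps, so identical configurations produce byte-identical
outputs.

## Known limitations

- The Louvain optimizer is exact only in the exhaustive-search sense on
  tiny graphs; on large graphs it inherits the usual local-optimum and
  resolution-limit caveats (hence the restart ensembles).
- The consensus fixed point can depend on the agreement structure in
  degenerate mixtures: with highly concentrated dwell profiles, distinct
  subjects can share a core partition (see the α discussion above).
- ICC assumes the two-way additive model; interaction-dominated tables
  yield negative estimates, which are reported rather than floored.
- BCa acceleration uses the jackknife; with heavy-tailed residuals at
  small n the intervals can undercover, which the coverage check bounds
  but does not eliminate.
- The transfer projection assumes the second cohort measures the same
  features on comparable scales; it re-standardizes but cannot correct
  differing reliabilities.
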