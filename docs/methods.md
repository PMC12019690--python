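# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limitations of `kelpshift`. It is the package's
own account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## The suitability model

`MaxNet` fits a presence–background maximum-entropy model: the Gibbs density
`raw(z) = exp(f(z)·β)/Z` over background cells, with β minimizing the
penalized negative presence log-likelihood

    J(β) = −(1/m) Σ_pres f(x)·β + log Σ_bg exp(f(z)·β) + Σ_j λ_j |β_j|.

Assumptions: occurrence cells are an (effort-unbiased) sample proportional
to suitability; background cells characterize the available environment
(default: all valid cells, capped at a seeded 50 000-cell sample); the
species–environment relationship is smooth enough for linear + quadratic +
product features. The intercept is implicit in the normalizer Z, so `raw`
sums to one over the training background by construction.

- **Features.** Linear, quadratic, and unordered pairwise products, columns
  in alphabetical variable order. Prediction-time inputs are clamped to the
  training range, so extrapolated cells behave like the nearest training
  condition. Constant features are excluded with a warning.
- **Penalty.** λ_j = multiplier × r(class, m) × sd_j/√m, where r is the
  published MaxEnt default schedule (shipped as
  `kelpshift/data/maxent_regularization.json`, interpolated in the presence
  count m and overridable) and sd_j is the feature's background standard
  deviation. The default multiplier is 1.
- **Solver.** Safeguarded cyclic coordinate descent with soft-thresholding
  on the standardized-feature problem (the penalty maps exactly because λ_j
  is proportional to feature scale). Because quadratic/product features are
  near-collinear with their parents, plain coordinate descent from zero
  converges too slowly; a split-variable L-BFGS-B phase (β = β⁺ − β⁻ with
  non-negativity bounds) supplies the warm start and is re-invoked if the
  descent stalls. Every accepted coordinate step is halved until the
  objective does not increase, so the recorded objective path is
  non-increasing. Convergence: objective change < 1e-8 per sweep or maximum
  coordinate update < 1e-6. The test suite checks the solver against an
  independent direct-search (Powell) minimizer on random small instances;
  the worst observed objective gap is ~1e-15 (tolerance 1e-4).
- **Outputs.** `raw`, and cloglog `1 − exp(−e^H·raw)` with H the entropy of
  the fitted background distribution. Response curves vary one variable over
  its training range with the others held at background means; ensemble
  response curves are averaged on a shared variable grid (averaging curves
  defined on each sub-model's own training range warps the curve and biases
  its argmax — this was a real defect caught during development). Ties in
  the argmax resolve to the lowest temperature.
- **Variable contribution** is permutation importance on training AUC:
  shuffle one variable's raw values across all points, rebuild features,
  average the AUC drop over seeded repeats, floor negatives at zero,
  normalize to percentages. The choice of metric is ours; "contribution to
  the model output" has no unique definition.

## Spatial block cross-validation

Folds are contiguous square blocks so spatially autocorrelated cells do not
straddle the train/test boundary. The block edge is chosen from an empirical
Moran-type correlogram of the temperature layer on a seeded cell sample: the
smallest candidate at least as large as the first distance where
autocorrelation falls below 0.1 (largest candidate, with a warning, if none
qualifies — the usual case for a field with a global latitudinal trend).
Blocks are shuffled with the seed and dealt round-robin into k = 5 folds;
assignment retries with an incremented seed (logged) until every fold holds
at least one presence cell. Background points inherit the fold of their
cell. Candidates over feature classes {L, LQ, LQP} × multiplier {1} are
scored by the mean train−test AUC gap (ties: higher test AUC, then fewer
classes); AUC is the rank-based Mann–Whitney form with ties counted ½, TSS
is sensitivity + specificity − 1 at the binarization threshold with
background treated as absence, computed per fold once the threshold exists.

## The tolerance transform and its calibration

The logistic warp `y = x + T_inc/(1 + exp(−r(x − p)))` is strictly
increasing in x, bounded by (0, T_inc), and equals T_inc/2 at the
suitability peak p, so the warped layer has no gaps or rank inversions.
`r` defaults to 2 per °C (the transition spans roughly ±2 °C around p);
the paper trail for this constant is config-exposed. Occurrences are never
moved; only the training temperature layer is warped, and projections always
use unmodified scenario layers.

T_inc is calibrated per tolerance target k so that the gain is real in the
operational sense: full-mode calibration bisects T_inc ∈ [k, k+10],
retraining the **fold ensemble** on the warped layer at each trial value and
measuring the ensemble response curve's upper crossing **at that ensemble's
own 95 %-capture threshold**, until the crossing sits k ± 0.05 °C above the
base ensemble's crossing at the base threshold. Consistently, the
binarization threshold of a shifted model scores occurrence cells in that
model's training environment (the warped present layer), exactly as the base
model is scored on its own training layer. Calibrating on single-model
curves at the base threshold — an earlier implementation — left the realized
ensemble crossing gains ~0.5 °C short on some seeds. A fast mode returns the
closed form T_inc = k·(1 + exp(−r(x_cross − p))) (exact when retraining
reproduces the base curve composed with the inverse warp, which the test
suite verifies analytically); it is used in tests and available in config.

## Binarization and accounting

The threshold is the ⌈0.95·n⌉-th largest occurrence suitability — the
largest value keeping ≥95 % of occurrence cells suitable (warned below 20
cells, where the order statistic is unstable). Cell areas are
`(res·π/180·R)²·cos(lat)` with R = 6371.0088 km (30.911 km² per 0.05° cell
at the equator). Lost = suitable now ∧ unsuitable in the future baseline;
contraction is reported overall and per basin (split at −40° W), with the
minimum suitable latitude per basin. Recovered area at tolerance k is
restricted to the lost set, so newly colonized habitat never inflates
recovery percentages; gained cells are reported separately. The
first-recovering-k map drives the incremental accounting, and unrecovered is
defined as lost minus the union of all recoveries, which keeps the identity
`lost = Σ incremental + unrecovered` cell-exact even if a cell's recovery is
non-monotone in k (permitted, counted, and logged as model noise).

## The synthetic world

The generator emulates the *structure* of the real inputs, not their
values: a maximum-SST layer with a monotone south-to-north cooling backbone
(27 °C at the southern edge, −2.0 °C per degree of latitude) plus smooth
seeded noise (Gaussian-blurred white noise, length scale 0.5°, sd 0.8 °C); a
salinity field (33 ± 2 PSS); a phosphate field; `degree_days`, a strictly
increasing transform of temperature (Spearman ρ = 1, so correlation pruning
always has a victim); `turbidity`, pure smooth noise (so the 5 % filter
always has a victim); and an eastern-biased elevation field giving 20 % land
and a coastal shelf, of which the cells ≤ 200 m deep form the validity mask.
Future scenarios add a uniform offset to temperature only (a
latitude-dependent option exists). Everything is a pure function of
(parameters, seed).

The planted truth is Gaussian in temperature (optimum 17.0 °C, sd 1.0 °C)
times a logistic in salinity (midpoint 33 PSS, slope 1.5 per PSS), scaled to
a maximum occupancy of 0.9. These conditions were set once, by two
considerations: the ratio of niche width to the regional temperature span
(~4 °C of usable niche against a ~23 °C span) matches a cold-temperate kelp
in a basin-scale study window, and the implied discrimination ceiling
(truth-scored AUC ≈ 0.91) is consistent with the discrimination actually
reported for such models; and the salinity response is strong enough
(~10 % contribution) to survive the 5 % filter, as it does for some real
species, while turbidity and phosphate (< 1 %) are filtered. Occurrences are
per-cell Bernoulli draws from the truth, accumulated over passes until the
target count is reached, then thinned uniformly (seeded) to exactly the
target — uniform thinning preserves the suitability-proportional density
that the χ² goodness-of-fit invariant checks.

What the synthetic world does *not* emulate: real bathymetry or coastline
geometry, sampling effort bias in occurrences, interannual climate
variability, non-uniform warming patterns (beyond the optional latitude
gradient), and dispersal limitation. Passing tests therefore demonstrate
that the pipeline recovers planted parameters and accounting identities
under clean conditions, not that real-data projections are unbiased.

## Problem sizes and defaults

The default study window is 200 × 300 cells at 0.05° (10° × 15°), ~35 000
shelf cells, ~500 occurrence records, 5 folds, tolerance targets +1…+5 °C,
and scenarios +1.5 °C and +3.0 °C — sizes at which the complete pipeline,
including full-mode calibration (≈9 ensemble refits per tolerance target),
runs in well under a minute on one CPU. The full North Atlantic window
(−85…50° E, 35…75° N) is available via `GridSpec.north_atlantic()` when real
rasters are supplied. Raster interchange uses ESRI ASCII grids (plain text,
north-up, nodata-tagged) rather than a binary raster format, and fitted
models serialize to JSON for exact reload.

## Known limitations

- Permutation importance is AUC-based and will understate a variable whose
  effect is strong but spatially confounded with temperature.
- The correlogram rule returns the largest candidate block size whenever a
  global environmental trend keeps autocorrelation above 0.1 at all lags;
  block size is effectively a config choice in that regime.
- Recovery of exactly k °C of warming by the k-calibrated family holds at
  the response-curve level; cells whose suitability is limited by the
  secondary variable can still fall short of the threshold after warming, so
  cumulative recovery at k = 3 under +3 °C warming is typically 97–100 %,
  not identically 100 %.
- The cloglog map is interpretable as occupancy probability only under
  assumptions (notably on prevalence) that the package does not verify.
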