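# Methods

## Problem and estimands

The estimand is the district-level proportion `θ_d` of ever-married women
aged 15–49 who experienced physical, emotional, or sexual intimate-partner
violence (IPV) in the previous 12 months. The survey design that motivates
the package interviews women nationwide but administers the violence module
to **one woman per household in a ~15% random household subsample**, so a
district's module sample is typically only ~100–200 women spread over ~10
PSUs — too small for reliable direct estimation. The package estimates `θ_d`
by area-level small-area estimation, and classifies spatial clusters of the
resulting map.

## Stages

### Direct estimation

Per district and outcome: the survey-weighted proportion
`p̂_d = Σw_i y_i / Σw_i`; a with-replacement first-stage Taylor-linearised
variance using PSU totals `z_j = Σ_{i∈j} w_i (y_i − p̂_d)`,
`v_d = m/(m−1) · Σ_j (z_j − z̄)² / (Σw_i)²`; the delta-method logit-scale
sampling variance `ψ_d = v_d/(p̂_d(1−p̂_d))²`; and a logit-scale Wald 95% CI.
Design choices: strata and finite-population corrections are ignored (the
synthetic design has none; this matches the common with-replacement
approximation for multi-stage surveys); districts with a single PSU or with
`p̂_d ∈ {0,1}` have undefined `ψ_d` and are treated as *unsampled* by the
model stage — they still receive synthetic predictions. Confidence intervals
are built on the logit scale so they respect (0,1) and match the model's
scale.

Cohort-flow accounting (`direct.cohort_flow`) reproduces the module's
sample-flow arithmetic — module uptake over all interviewed women, and
never-married / privacy exclusions over the module sample — with percentages
rounded to one decimal.

### Area-level model

The logit-transformed Fay–Herriot model
`logit(p̂_d) = x_d'β + u_d + e_d`, `u_d ~ N(0, σ_u²)`, `e_d ~ N(0, ψ_d)` with
`ψ_d` treated as known. A unit-level mixed model is not an option here
because auxiliary data exist only as district aggregates; the area-level
model is the standard formulation for that situation. Estimation is profile
maximum likelihood: for a candidate `σ_u²`, `β` is the GLS solution and the
profile criterion is minimised over `σ_u² ∈ [0, 10·var(y)]` by bounded Brent
search; a restricted-likelihood (REML) criterion is available by flag. ML is
the default for determinacy; at a few hundred districts the difference is
immaterial and is covered by a test. A likelihood maximised at `σ_u² = 0` is
reported as a boundary fit, not jittered. The EBLUP is
`η̂_d = x_d'β̂ + γ_d(logit p̂_d − x_d'β̂)` with `γ_d = σ̂_u²/(σ̂_u² + ψ_d)`;
out-of-sample districts get `γ_d = 0`. State of residence enters as one-hot
fixed effects (first state id in sort order as reference).

Back-transformation is plain `expit(η̂_d)` by default, for transparency; a
bias-corrected option integrates expit over `N(η̂_d, mse_d)` with 41-node
Gauss–Hermite quadrature.

MSE estimation is a parametric bootstrap (default B = 200, acceptance runs
use 200–500): redraw `u* ~ N(0, σ̂_u²)` for every district and
`e* ~ N(0, ψ_d)` for sampled ones, refit, re-predict, and average the squared
logit-scale error against the replicate's own truth `x'β̂ + u*`. CIs are Wald
on the logit scale with the bootstrap MSE; the CV is the delta-method
root-MSE on the proportion scale divided by `θ̂_d`. Refit failures above 10%
of replicates abort with the rate.

### Diagnostics

Model diagnostics: standardised residuals
`(logit p̂_d − x_d'β̂)/√(σ̂_u² + ψ_d)` with Shapiro–Wilk (normality) and
Breusch–Pagan against the predicted values (homoskedasticity); "randomly
distributed residuals" is operationalised as these two tests, with judgement
left to the caller. Estimate diagnostics: OLS of the **direct** estimates
(y-axis) on the **model-based** estimates (x-axis) on the proportion scale,
with t-tests of slope = 1 and intercept = 0 — regressing the noisy
measurement on the stable predictor, the standard orientation for this
check; per-district CV and CI-width comparisons; and the per-state
coefficient of variation of model-based estimates (population SD over mean —
a descriptive quantity, hence divisor n).

A caveat worth stating: the slope-vs-1 diagnostic is exactly calibrated only
when the fitted model is correctly specified *including* the `ψ_d` values.
The EBLUP shares the direct estimate's sampling noise, which biases the OLS
slope upward by roughly `γψ/(V_x + γσ_u²)` (with `V_x` the covariate-signal
variance); when `ψ_d` must itself be estimated from ~10 PSUs, the extra noise
inflates `σ̂_u²` and the test over-rejects. The calibration experiment
(`pipeline.diagnostic_calibration`) therefore fixes a realistic design and
redraws the direct estimates exactly from the model; through the full survey
machinery the same test rejects more often than its nominal size. The
diagnostic is informative when covariate signal dominates shrinkage — the
regime the package's generator defaults emulate (see below).

### Geometry

Queen contiguity (order 1, row-standardised) — the default in the LISA
literature; districts sharing any boundary point are neighbours, isolates
are listed and excluded from standardisation. The **border proximity factor
(BPF)** of a district is the mean, over points placed uniformly by arc
length along the district boundary (default 256), of the Euclidean distance
to the district's own state border. "Distance of a district from the state
border" admits several readings (centroid, area mean, boundary mean); the
boundary mean is the default as the closest literal reading, and a centroid
variant is available (`bpf_method="centroid"`). The study-area outer frame
is *excluded* from state borders by default — BPF is motivated by
cross-state similarity, which only interstate borders mediate, so a coastal
district far from any interstate border keeps a large BPF; a flag flips
this (required for single-state maps). Distances are planar map units;
geodesic computation is out of scope.

### LISA

Univariate local Moran's I, re-implemented (not wrapped):
`z_i = (x_i − x̄)/s` with the population SD over valid districts,
`I_i = z_i · Σ_j w_ij z_j`. Inference is by conditional permutation (hold
`z_i`, permute the remaining values into the neighbour slots; default 999
permutations), pseudo p-value `(count + 1)/(n_perm + 1)` on the one-sided
tail matching the sign of `I_i` — the conventions of the common desktop
implementation. Significant districts are classified by the signs of
`(z_i, lag_i)` into high-high, low-low, high-low, low-high; others are
not-significant; isolates are "neighbourless" with undefined `I_i`. No
multiple-testing correction by default (matching standard LISA maps); a
Benjamini–Hochberg option exists. An exact-enumeration oracle
(`exact_permutation_check`, n ≤ 8) validates the Monte-Carlo engine.

### Pipeline

`run_all` chains synth → geometry → direct → areamodel → diagnostics → lisa
with per-stage seeds derived from the master seed by fixed offsets, so
stages re-run in isolation reproduce the pipeline bit for bit; a manifest
records the config hash, seeds, files, and row counts. The three outcomes
are processed as independent univariate analyses (separate models and maps
per outcome). On failure, artifacts already written are renamed with a
`.partial` suffix and the failing stage is named.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
known truth:

- **Geography**: rectangular district cells tiling a rectangle, one
  contiguous block (as square as the count allows) per state, blocks stacked
  vertically. This guarantees a connected queen graph, well-defined
  interstate borders, and within-state BPF variation.
- **Covariates**: census-style district aggregates (caste/tribe share,
  religion, workforce and literacy levels and sex gaps, household headship
  and size, male out-migration, age at marriage, male-birth share, sex ratio
  at birth, urban share, a socioeconomic index), each a Gaussian-copula
  transform of a Gaussian random field over district centroids with
  correlation `exp(−d/spatial_range)` — so covariates are proportions on
  realistic ranges and spatially clustered prevalence surfaces (hence LISA
  clusters) exist. Default `spatial_range = 3` map units (a few district
  widths).
- **Truth**: `logit θ_d = x_d'β + u_d`, `u_d ~ N(0, σ_u²)`, holding exactly
  per district. Defaults `β = (0.5, −4.0, +2.0)` on (intercept, female
  literacy, SC/ST share) and `σ_u = 0.15` give prevalences centred near 22%
  ranging roughly 5–60% — matching the mean (22.5%) and district range
  (~1–48%) reported for 12-month physical IPV in the national study this
  emulates, with literacy protective and caste-share positive as in that
  study's subgroup gradients. Emotional and sexual IPV share the surface
  with logit offsets −0.85 and −1.7 (≈11% and ≈5% at the centre).
- **Survey**: per district, 10 PSUs × 100 households; each household enters
  the module subsample independently with probability 0.15 and contributes
  one respondent (~150 expected respondents/district — the intended scale of
  the emulated module). Outcomes are Bernoulli with a multiplicative
  log-normal PSU effect (SD 0.1, clipped to keep probabilities in (0,1)),
  which induces design effects above 1 while leaving `θ_d` the exact
  district estimand. Design weights are log-normal with CV 0.3, renormalised
  to mean 1 within district — reproducing unequal weighting without a full
  multi-stage weighting scheme. Weights are emitted already valid for the
  subsample (no post-hoc renormalisation question arises).

What the generator does **not** emulate: stratification and non-response
adjustment, state-level weight normalisation, informative sampling,
measurement/reporting error in self-reported IPV, irregular real-world
polygons, or spatially correlated area effects (u is iid). Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions plus moderate design effects — not robustness to the full messiness
of real survey data.

## Numerical choices and degenerate inputs

- Variance optimisation: bounded Brent with `xatol = 1e-10`; the boundary
  `σ_u² = 0` is accepted whenever its criterion is within `1e-9` of the
  interior optimum; convergence requires the optimum to be a local minimum
  up to `1e-6`.
- `γ` is defined as 0 when `σ_u² + ψ = 0`.
- Bias-regression t-tests: a standard error below `1e-10` is treated as an
  exact fit (t = 0, p = 1 when the estimate equals the null; immediate
  rejection otherwise).
- Rank-deficient designs abort with the offending columns (QR-pivot
  heuristic); the covariate generator retries up to 5 seeds if its copula
  fields are degenerate.
- LISA: constant surfaces are an error (zero variance); missing values on
  districts with neighbours are excluded from the mean/SD and flagged, and
  their neighbours' lag weights are renormalised.
- Single-district states report CV = 0 with a flag; empty districts are
  "unsampled", not errors.

## Problem sizes

Default demo: 36 districts in 6 states (~5 400 respondents). Monte-Carlo
experiments: 50 replicates at 100 districts (5 states × 20) with ~150
expected respondents per district, bootstrap B = 200 — chosen as the
smallest sizes at which Monte-Carlo standard errors are tight enough for
3-SE recovery checks and coverage assessment, while a full test run stays in
the minutes range. The recovery experiment uses
`β = (−1.2, 0.8, −0.5), σ_u = 0.3` — moderate effects that make every
component's recovery informative (the default β's large literacy effect
would dominate the signal).

## Known limitations

- The MSE bootstrap ignores the uncertainty of `ψ_d` (treated as known, as
  the model assumes); with ~10 PSUs per district `ψ̂_d` is noisy and
  coverage can drift towards the lower end of the nominal band.
- ML variance estimates carry the usual O(p/n) downward bias; REML is
  available but not the default.
- The naive expit back-transformation is median- not mean-unbiased; the
  Gauss–Hermite correction addresses this but changes `θ̂` only noticeably
  for high-MSE districts.
- No benchmarking of district estimates to state direct estimates, no
  spatially correlated random effects, no replication-weight variances —
  all deliberately out of scope.
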