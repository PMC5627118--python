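# Methods

## The statistical problem

Annual overwinter abundance of the eastern migratory monarch butterfly
is indexed by the log area (ha) of occupied oyamel fir forest,
observed for ~22 years. Candidate explanations number in the dozens
per breeding region and fall into two regimes: slowly evolving
"trend" covariates (cumulative glyphosate, dicamba, 2,4-D and
neonicotinoid application, cumulative overwinter forest loss,
Conservation Reserve Program area), which are monotone and nearly
collinear across regions, and stochastically varying climate
covariates (temperature summaries over phenological windows, degree
days, drought indices, overwinter storm weather), which are correlated
within a region. With p ≈ 76 ≫ n ≈ 22 and severe multicollinearity,
attribution requires (i) filling historical gaps, (ii) y-aware
dimension reduction, (iii) information-criterion inference over small
candidate models, and (iv) a mechanistic path model for the leading
driver. Each stage is a module; each module is usable on its own.

## Gap filling (DINEOF)

Missing covariate cells are reconstructed by data-interpolating
empirical orthogonal functions. The year-by-variable matrix is
standardized column-wise, truncated to its leading k singular modes,
and the missing cells overwritten by the reconstruction, iterating to
a fixed point; k is selected by withholding a fraction (default 0.05)
of *observed* cells as reference values and minimizing their RMSE
(ties to the smaller k), after which the chosen k is refitted with all
observed cells participating.

Numerical choices that matter:

- **Standardization constants are re-estimated from the completed
  matrix at every iteration** rather than fixed from the gappy data.
  With constants frozen at the observed-cell statistics, a masked
  column's off-center mean places it outside the span of the complete
  columns, and exactly low-rank matrices — the regime in which matrix
  completion is identifiable — become non-recoverable: any fill value
  then yields the same rank. Re-estimation makes the exact completion
  the unique attracting fixed point in that regime and is the natural
  EM treatment of means and scales under missingness.
- **Modes are added incrementally**: the iteration for k modes is
  warm-started from the converged (k−1)-mode solution, as in the
  classical DINEOF recursion. Truncated-SVD completion has multiple
  fixed points; cold starts at the column mean can land on spurious
  ones when trailing singular values are weak.
- Convergence: relative change in the RMS update of fillable cells
  below `tol` (default 1e−6), cap 500 iterations; non-convergence is
  reported by a `RuntimeWarning` and a flag, and the best iterate is
  returned. Large k relative to the matrix size frequently fails to
  converge — harmlessly, since cross-validation then rejects those k.
- Columns are standardized because covariates mix units (kg, ha, °C,
  proportions); the reference-cell RMSE is likewise measured on the
  standardized scale so no column dominates the selection.
- The response series is never imputed; it is complete by
  construction.

## PLS1 variable reduction

NIPALS for a univariate response: component weight w ∝ X′y (unit
norm), score t = Xw, x-loading p = X′t/t′t, y-loading q = y′t/t′t,
deflating both X and y. X and y are standardized (n−1 denominator);
the regression vector B = W(P′W)⁻¹q is back-transformed to the
original scale. Component c explains 100·q_c²·t_c′t_c/TSS percent of
response variance. "Loading" for selection is the Pearson correlation
of each *undeflated* standardized predictor with each score — the
correlation-loading scale on which the ≥0.15 threshold operates —
while NIPALS x-loadings are reported separately.

Leave-one-out cross-validation refits the model on every size-(n−1)
subsample with centering and scaling re-estimated inside the fold (no
leakage), giving PRESS and Q² = 1 − PRESS/TSS with TSS about the
full-sample mean. A fold that zeroes a column's variance drops that
column within the fold and flags it.

Selection applies the threshold rule first and the top-10-per-
component cap second, then prunes the union: variables with pairwise
|r| > 0.6 are clustered transitively and one representative kept per
cluster, preferred by breeding-region priority (north-central first,
since it hosts the bulk of summer breeding), then by larger absolute
loading, then lexicographically — fully deterministic. The default of
two components reflects the two-regime (trend + climate) structure of
the covariates; Q²-based selection is available via configuration.

## Best-subset Gompertz inference

The response model is `N_t = α₀ + β′X_t + ε_t` with N the natural log
of occupied area; dependence on `N_{t−1}` (density dependence) enters,
when desired, as an ordinary candidate covariate rather than a forced
term. Covariates are standardized so coefficients are comparable;
the response stays in log ha. Each subset is fitted by least squares;
`logLik = −(n/2)(log(2πσ̂²) + 1)` at the ML variance σ̂² = RSS/n, and
`BIC = −2 logLik + k ln n` with **k = covariates + 2**, charging for
the intercept and the residual variance — the only parameter-count
convention internally consistent with the published model table at
n = 22. Exactly collinear subsets are flagged singular and excluded
from ranking (their Gaussian ML is degenerate) rather than fitted by
pseudo-inverse.

Weights are ωᵢ = exp(−Δᵢ/2) normalized over the enumerated set;
variable importance is the summed weight of models containing the
variable; model-averaged coefficients sum ωᵢβ̂ᵢⱼ with zeros for absent
terms, which shrinks weakly supported effects toward zero in
proportion to importance (a confidence-set-only averaging mode is
exposed). The confidence set keeps models within 10 BIC units of the
best, ties broken by fewer covariates then lexicographic subset.
Enumeration supports both "all subsets up to size 4" (default; the
sample size caps model complexity) and "exactly size 4"
(C(11,4) = 330 models); both readings are exposed because top models
in practice carry 2–3 covariates while the full exact-4 space is the
printed count.

Residual diagnostics: sample ACF (statsmodels) with ±1.96/√n bounds
and a flag for any lag ≥ 1 outside them, and an exact-ML AR(1)-error
refit — profile likelihood over φ ∈ (−1, 1) via the stationary
Prais–Winsten transform including the ½·log(1−φ²) first-observation
term, coarse grid then bounded local refinement, k = covariates + 3 —
reported as a ΔBIC against the white-noise fit.

## Structural path model

The recursive chain x → m → y (log cumulative glyphosate → log
milkweed → log population) is a covariance-structure model on
standardized variables with five free parameters (γ, δ, three
variances) against six sample moments, so the omitted direct x → y
path leaves df = 1. For a recursive system with diagonal residual
covariance, ML equals per-equation least squares; the discrepancy
`F_ML = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − 3` is scaled by (n−1)
(Wishart convention; an n-multiplier switch exists, and at the
magnitudes involved the choice cannot move any index at two decimals).
`RMSEA = √(max(χ²−df,0)/(df(n−1)))`; `CFI = 1 − max(χ²−df,0) /
max(χ²_b−df_b, χ²−df, 0)` against the independence baseline (free
variances, all covariances zero), whose discrepancy reduces to
−log|R| for the sample correlation matrix (df_b = 3). Any model with
χ² ≤ df therefore scores RMSEA = 0 and CFI = 1 exactly. Intercepts are
excluded (standardized, covariance-only fit), matching the reporting
of standardized coefficients. Exactly deterministic chains make S
singular; when the implied covariance reproduces S the fit is scored
as perfect (χ² = 0) instead of failing.

Note that a genuinely standardized simple-regression slope cannot
exceed 1 in magnitude; published path coefficients larger than 1 with
sub-unity R² indicate a different (unstandardized or per-annum)
scale, so recovery tests compare estimates against the standardized
truth implied by the generator rather than against printed values.

## The synthetic-data generator

`simulate_dataset` emulates the study's data structure from a declared
ground truth:

- **Trend covariates**: logistic adoption curves (annual application;
  rate U(0.4, 1.2), midpoint U(0.3n, 0.7n), level U(0.5, 2)) cumulated
  over years; covariates sharing a base curve across regions differ
  only by 2% multiplicative noise, reproducing the r > 0.99
  cross-region collinearity of real cumulative-application series.
- **Climate covariates**: AR(1) over years (φ = 0.3) sharing a
  per-region factor at the configured within-block correlation.
- **Response**: `N_t = α₀ + φ·N_{t−1} + Σ βⱼ z_{jt} + ε_t` on
  *standardized* covariates z, ε white noise; defaults n = 22 years
  (the 1993–2014 span), σ = 0.3 log ha, φ = 0. Density dependence is
  written out explicitly even though a lag covariate can carry it, so
  generator truth is unambiguous for recovery scoring.
- **Missingness**: per-variable masked-year counts drawn uniformly
  without replacement (or a "tail" mode masking final years, matching
  covariates whose sources end early); the response is never masked.
- **Milkweed chain**: `simulate_milkweed_series` generates log
  milkweed downstream of log cumulative glyphosate with a configurable
  γ, mirroring the path model's causal structure.

`reduced_study_config` is the reference truth for recovery studies: 11
covariates (one cumulative trend + ten climate, within-block
correlation 0.3, all north-central), three of them active with
standardized effects (−0.5, −0.13, −0.14), emulating the
*post-reduction* variable set — the pipeline's own |r| > 0.6 pruning
guarantees the reduced set is not strongly collinear and keeps a
single representative per trend cluster, so a single dominant trend
covariate is the realistic regime. Recovery studies use 22-year
replicates for confidence-set coverage and 200-year replicates for
coefficient recovery; the path-model null calibration uses 200
replicates of n = 1000.

What the generator does **not** emulate: real phenological-window
engineering (climate covariates are abstract AR(1) series, not GDD
sums over calendar windows), historically clustered missingness
beyond the tail mode, observation error in the response (the real
index is itself a state-space estimate), and regional weighting of
sites. Passing recovery tests therefore demonstrate that the pipeline
recovers truth under the assumed covariance regime — not that the
published real-data coefficients are correct.

## Degenerate inputs and tie-breaks

Zero-variance predictors are rejected (PLS) or flagged (folds,
correlation filter); the DINEOF identity holds bit-exactly on complete
matrices; weight normalization excludes non-finite BICs; mode-count
and cluster-representative ties resolve to the smaller k and the
deterministic (region, |loading|, name) key respectively; all
randomness flows from explicit seeds, with the pipeline splitting one
root seed into per-stage seeds via `SeedSequence.spawn`.

## Known limitations

- DINEOF at large k on small matrices often hits the iteration cap;
  the warning-plus-best-iterate policy leaves selection to the
  cross-validation curve.
- The AR(1) profile grid (39 points, ±0.06 refinement window) is
  adequate for |φ| ≤ 0.95 but not tuned for near-unit-root errors.
- The correlation filter is greedy-transitive: a chain a–b–c with
  |r(a,c)| < 0.6 still collapses to one representative.
- PLS component count is fixed (default 2) rather than selected per
  dataset unless Q² selection is requested.
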