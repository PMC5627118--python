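# monarch-threats

Threat attribution for the eastern migratory monarch butterfly
(*Danaus plexippus*). The overwintering population is surveyed each
December as the area (ha) of Mexican oyamel fir forest occupied by
colonies; over roughly two decades the log of that area declined while
dozens of candidate threats — herbicide-driven milkweed loss,
overwinter forest loss, insecticide use, parasitism by *Ophryocystis
elektroscirrha*, and climate variation across the breeding regions —
changed alongside it. With ~22 annual observations and ~76 collinear
covariates, ordinary regression cannot attribute the decline. This
package implements, as a tested and reusable pipeline, the multi-stage
analysis that can:

1. **Gap filling** (`monarch_threats.impute`) — DINEOF: iterative
   truncated-SVD reconstruction of missing covariate cells, with the
   number of EOF modes chosen by cross-validation against withheld
   observed cells.
2. **Variable reduction** (`monarch_threats.pls`) — partial
   least-squares regression (PLS1 via NIPALS), a *y-aware* dimension
   reduction whose components maximize covariance with log population
   size. Performance is scored by fitted R², leave-one-out
   PRESS = Σᵢ(yᵢ − ŷᵢ/ᵢ)² and Q² = 1 − PRESS/TSS; variables are
   selected by correlation loading (|loading| ≥ 0.15, top 10 per
   component) and pruned so no two survivors correlate above |r| = 0.6.
3. **Best-subset time-series inference** (`monarch_threats.modelsel`) —
   the Gompertz log-abundance model `N_t = α₀ + β′X_t + ε_t`,
   `ε_t ~ N(0, σ²)`, fitted exhaustively over all small covariate
   subsets (11 variables taken 4 at a time gives C(11,4) = 330 models),
   ranked by BIC = −2 logLik + k ln n with k = (covariates + 2), and
   summarized by BIC weights ωᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2), variable
   importance (summed weights), shrinkage model averaging, a ≤10-ΔBIC
   confidence set, residual ACF diagnostics, and an exact-ML AR(1)-error
   alternative.
4. **Structural path model** (`monarch_threats.pathmodel`) — the
   recursive log-log chain
   `log(milkweed) = γ·log(cum. glyphosate)`,
   `log(population) = δ·log(milkweed)`, fitted as a covariance-structure
   model; the single omitted direct path is tested by the ML χ² on
   1 df with RMSEA and CFI.
5. **Synthetic data** (`monarch_threats.datagen`) — a generator that
   emulates the study's data structure (near-collinear cumulative trend
   blocks, AR(1) climate blocks, configurable missingness, Gompertz
   response with declared ground truth), plus the covariate-engineering
   transforms: growing degree days (base 11.5 °C, cap 36 °C), lethal
   degree days (≥38 °C threshold, minus 37), annualization of multi-year
   forest-loss totals.

The assembled real covariate table is not publicly deposited, so the
pipeline is exercised end-to-end on synthetic data with known truth,
and the published model-selection table and fit statistics are verified
by internal-consistency recomputation.

## Worked example

```sh
monarch-threats run-all --config demo.yaml --seed 11 --outdir demo_out
```

with `demo.yaml`:

```yaml
simulation:
  n_years: 22
  n_trend_covariates: 1
  n_climate_covariates: 10
  regions: [north_central]
  true_coefficients:
    trend_0_north_central: -0.5
    climate_0_north_central: -0.13
    climate_1_north_central: -0.14
  noise_sd: 0.3
  within_block_correlation: 0.3
  missing_counts: {climate_2_north_central: 3}
impute: {max_modes: 6}
select: {max_size: 4}
sem:
  derive: {glyphosate: trend_0_north_central, gamma: -0.6, noise_sd: 0.3, seed: 1}
```

prints (abridged):

```
INFO impute: {'n_modes': 1}
INFO pls: {'fitted_r2': 0.679, 'q2': 0.252, 'n_candidates': 11, 'reduced_variables': [...8 variables...]}
INFO select: {'n_models': 162, 'n_confidence_set': 41,
              'best_subset': ['climate_0_north_central', 'trend_0_north_central'],
              'best_r2': 0.684, 'best_bic': 24.93}
INFO sem: {'gamma': -0.971, 'delta': 0.649, 'chi2': 0.709, 'cfi': 1.0, 'rmsea': 0.0}
```

Reading: three missing climate cells were filled with one EOF mode; two
PLS components fit 68% of the response variance in-sample (Q² = 0.25
out-of-sample at this noise level); correlation pruning left 8 of the
11 covariates, and among all subsets of up to four of them the
best-supported Gompertz model contains the true dominant trend
covariate plus one active climate covariate (variable importance 0.999
and 0.907 in `importance.csv`). The path model fitted to a milkweed
series generated downstream of the cumulative trend covariate accepts
the no-direct-path structure (χ²₁ = 0.71, CFI = 1.0, RMSEA = 0).
Every artifact (model table, loadings, importance, ACF report, path
fit, manifest with per-stage digests) is plain CSV/JSON in `demo_out/`;
rerunning with the same config and seed reproduces identical digests.

Individual stages are also available as `monarch-threats simulate`,
`impute`, `pls`, `select` and `sem` on plain CSV files, and the same
operations can be called as library functions.

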