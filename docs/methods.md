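# Methods

## Model and assumptions

The package targets out-of-sample prediction of a fully observed
response `Y` from `p` numeric predictors `X` with arbitrary missingness.
Missingness is recorded in an indicator matrix `M` with `M[i,j] = 1`
meaning *missing* (the pattern-mixture convention; the reverse of the
"1 = observed" habit — stated here once and relied on everywhere).
Responses must be observed; missing-`Y` problems are out of scope, as
are categorical predictors.

The pattern-mixture factorization
`P(Y, M | X) = P(Y | X, M) · P(M | X)` motivates the pattern submodel
(PS): fit the kernel `E[Y | X_M, M = m]` separately within each
observed pattern `m`, using only that pattern's records and observed
columns. Because the expected loss decomposes as
`Σ_m P(m) · E[L | m]`, per-pattern loss minimization is overall loss
minimization *within a fixed model class*; accordingly a model set
never mixes learner classes across patterns (one `BaseLearner` — family
linear or logistic, variant plain or relaxed lasso — per set).

The comparison strategies follow the standard taxonomy: CCS re-uses all
records observing a pattern's columns (valid under an MCAR-type
assumption), the complete-case model needs deployment-time imputation,
and MIMI re-parameterizes the pattern-specific means into direct
effects `β` plus auxiliary indicator effects `δ` (for `p = 2`:
`E[Y|X,M] = β0 + β1x1 + β2x2 + δ1m1 + δ2m2 + δ3x1m1 + δ4x2m2 + δ5x1m2 + δ6x2m1`).
Under MCAR the true `δ` are all zero. With single conditional-mean
imputation the MIMI forecasts reduce algebraically to PS forecasts
(e.g. the x1-missing submodel slope satisfies
`γ2 = β2 + δ6 + (β1 + δ3)·α2` where `E[X1|X2] = α0 + α2X2`); the test
suite verifies this to machine precision, including the coefficient
identity. One difference is retained deliberately: PS stores a separate
residual variance per pattern, while MIMI forces a common one.

## Synthetic-data generator

The generator emulates a two-covariate Gaussian study: `n` draws from
`N(μ, Σ)` with defaults `μ = (3, 3)` and unit variances with
correlation `ρ = 0.5`; a linear outcome `Y = β0 + β1x1 + β2x2 + ε`,
`ε ~ N(0, 1)`, with the headline effect sizes `β = (1, 3, 1)`; and
missingness confined to `x1` with target rate `P(M1 = 1) = 0.5`. Under
the pattern-mixture formulation the outcome mean is instead the
indicator-augmented model evaluated at the true `X` and the simulated
`M`, with auxiliary effects `δ1 = δ3 = 1` (an intercept and x1-slope
shift in the missing pattern) — the configuration in which PS's
advantage is clearest.

Five mechanisms are simulated. MCAR uses a constant probability.
MAR / MNAR / MARY / MNARY use a logistic model whose drivers are,
respectively, the observed covariate (`ν2·x2`), the missing one
(`ν1·x1`), and those plus the response (`+ ν_Y·Y`); all driver
coefficients default to 1. The logistic link is this package's choice
(the selection-model standard; the calibration map is monotone under
it). The intercept `ν0` is calibrated by bracketing root-finding so the
*realized* mean probability over the in-sample drivers hits the target
rate; the calibrated intercept is then reused unchanged for the
out-of-sample population, keeping the mechanism consistent across the
two. Mechanisms that include `Y` can only be simulated under the
selection formulation, where `Y` exists before `M`; the spec-level
generation order is X→Y→M (selection) and X→M→Y (pattern mixture),
with separate child random streams for predictors, missingness and
noise so a mechanism change never perturbs the predictor draw.

What the generator does *not* emulate: non-Gaussian or categorical
predictors, more than one simultaneously missing covariate per
mechanism (the API supports per-column mechanisms, but the study
designs use one), longitudinal dropout, and measurement error. Passing
simulation checks therefore demonstrates correctness of the machinery
and the mechanism-dependence of the strategy ranking, not performance
on any particular clinical table.

## Imputation engines

Engines are frozen at fit time: column means, per-pattern conditional
OLS regressions (fit on the rows where the target and the pattern's
observed columns are all present), and PMM donor pools (observed target
values sorted by fitted mean). Out-of-sample records are imputed one by
one; for PMM each record's donor draws come from a stream seeded by the
engine seed plus a hash of the record's own cells, so batch and
one-at-a-time imputation agree exactly. Defaults: `k = 5` donors
(conventional), `m = 10` imputation sets for PMM, uniform draw among
the `k` nearest donors by |fitted − predicted| — the matching metric is
a declared choice, not canon. A record whose pattern has no fitted
conditional model falls back to the unconditional mean with a logged
warning. The Bayesian conditional-mean variant takes a single
flat-prior posterior draw of the coefficient vector at fit time (so it,
too, is frozen).

In-sample multiple imputation is chained-equations PMM: columns visited
in order of increasing missingness, 10 cycles per set (configurable;
with a single incomplete column the chain converges immediately),
initialized by random draws from each column's observed values. `Y` may
be included as a chained-equations regressor via a flag; it is off by
default because the out-of-sample `Y` is unknown. This choice matters:
with `Y` excluded the imputation model is uncongenial with the analysis
model and MIMI/MI coefficient estimates are attenuation-biased even
under MCAR (the fits remain fine *as predictors* for MIMI, whose
pattern terms decouple, but the `δ ≈ 0` check under MCAR is only a
fair test with the `Y`-inclusive engine, which is what the acceptance
check uses).

## Numerical choices

* All linear fits use pivoted-QR detection of aliased columns
  (relative tolerance `1e-8` on the R diagonal); aliased coefficients
  are set to 0 and recorded, never fatal. This matters structurally:
  conditional-mean completion makes the MIMI design exactly rank
  deficient (the imputed column is a linear function of the others
  within its pattern), and the min-norm/projection fit is what makes
  the PS equivalence hold anyway.
* A PS pattern with fewer records than coefficients raises, pointing
  at the hybrid; the hybrid rule is "PS when the pattern holds strictly
  more than `threshold` records" (default `2p`), so `threshold = 0`
  reduces to pure PS and `threshold = ∞` to pure CCS, and with the
  `(p+1)·2` convention a pattern at exactly the threshold gets CCS.
* Unseen patterns at forecast time get a CCS submodel fit on demand
  from the retained training data (configurable to a hard error).
* The MIMI interaction scope defaults to the full `X_j × M_k` set for
  `p ≤ 2` and to own-interactions (`X_j × M_j` plus indicator mains)
  above, where the full set grows as `p²`; both are available.
* Relaxed lasso: covariates standardized inside the CV'd lasso stage
  (penalty fixable for testing), unpenalized refit on the selected
  support on the original scale; empty support → intercept-only.
* Logistic fits are unpenalized lbfgs ML; a single-class or
  zero-feature pattern yields the intercept-only empirical-rate model.
* The logarithmic score is reported as *negative* mean Bernoulli
  log-likelihood (smaller is better, matching the Brier orientation),
  with probabilities clipped to `[1e-15, 1 − 1e-15]` so a confident
  wrong prediction is enormous but finite.
* Cross-validation folds are stratified by pattern (patterns smaller
  than `k` are logged and spread round-robin); lasso tuning is nested
  inside training folds.
* Rubin's rules pool MIMI coefficients (mean) and variances
  (within + `(1 + 1/m)` between).

## Simulation study sizes

The repeated study fits every strategy on an in-sample population,
freezes the engines, and scores one-by-one forecasts on a fresh
out-of-sample population under the same calibrated mechanism, recording
per-pattern losses, Monte-Carlo SEs, and the squared imputation error
of the missing covariate as a side channel (separating imputation bias
from prediction bias). The default repetition count is 1000 and
configurable; the shipped acceptance checks use 200 repetitions at
`n = n_out = 1000`, which puts Monte-Carlo SEs near 0.02–0.07 on mean
total errors of 4–115 — ample for the ordering and equivalence
conclusions they draw. Mechanism calibration is checked at `n = 10⁵`
(tolerance 0.02) and the coefficient-level checks at `n = 5000`.

Two equivalence facts are checked statistically rather than exactly:
PS and CCS coefficients agree under MCAR (within 3 Monte-Carlo SEs over
100 repetitions), and under MCAR/MAR the pattern-respecting strategies
(PS, CCS, MIMI, complete-case + conditional mean) have indistinguishable
mean total prediction errors. Finite-`m` multiple imputation is *not*
in that equivalence class even under MCAR: averaging `m = 10` PMM draws
leaves irreducible imputation variance of order `β1²·Var(x1|x2)/m` in
the missing pattern (plus attenuation from the `Y`-free chain), a gap
of roughly 1.1 loss units in the headline configuration that 200-rep
precision resolves easily. Its totals are still computed and reported.

## Known limitations

* Sparse patterns: PS within a small pattern is variance-limited; the
  hybrid threshold is a rule of thumb, not an optimality result.
* No shrinkage or inference machinery for the auxiliary `δ`
  parameters; MIMI standard errors are for the MCAR null check only.
* The PMM matching rule (nearest-`k`, uniform draw) and the chained
  cycle count are conventional defaults; other MICE implementations
  differ in detail.
* Serialization ships coefficients, means and donor pools — PMM donor
  pools embed observed covariate values, so a serialized PMM engine is
  not free of training data (PS/CCS models are).
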