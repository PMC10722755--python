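# Methods

## The model

A positive outcome `Y` (costs, lengths of stay, waiting times) is modelled
as gamma distributed with shape `α > 0` and scale `β > 0`:

    f(y) = y^(α−1) e^(−y/β) / (Γ(α) β^α),   E(Y) = αβ,   V(Y) = αβ².

A support shifted to `(L, ∞)` is obtained by replacing `y` with `y − L`;
`L` is accepted as a fixed user-supplied constant (default 0), never
estimated.

For a single distribution the variance can be written equivalently as
`E(Y)²/α` or as `β·E(Y)`. The two forms stop being equivalent once
covariates enter, because a regression must route covariate effects through
`α`, through `β`, or through both:

* **scale model** — `β(x) = exp(θ'x − log α)`, `α` constant:
  `V(Y|x) = E(Y|x)²/α`. This is the classical gamma GLM with log link;
  variance proportional to the squared mean.
* **shape model** — `α(x) = exp(θ'x − log β)`, `β` constant:
  `V(Y|x) = β·E(Y|x)`. Variance directly proportional to the mean.
* **shape/scale model** — `α(x) = exp(θ_α'x)`, `β(x) = exp(θ_β'x)`; nests
  both single-parameter models (a block of zero slopes recovers each).

All three share the same log-link regression function
`E(Y|x) = exp(b'x)` — for the single-parameter models `b` equals the varied
block's coefficients with the intercept shifted by the auxiliary log
constant, and for the shape/scale model `b = θ_α + θ_β`. What differs is
the mean–variance relationship imposed *across* covariate values. Fitting
the wrong parameterization leaves the quasi-score for the mean intact
(slopes stay consistent) but distorts the weighting, which inflates
finite-sample bias and sampling spread and makes the model-based standard
errors inconsistent.

### Reporting convention

`FitResult` stores the varied block's coefficients on that parameter's log
scale plus the auxiliary log constant (`log β` for the shape model, `log α`
for the scale model). Because users of log-link cost models read
coefficients as effects on the log conditional mean, every fit also exposes
`mean_coefficients` / `mean_standard_errors`: slopes are identical, the
intercept is the varied-block intercept plus the auxiliary, and SEs follow
by the delta method (exact, since the map is linear). The Monte Carlo
harness summarizes this mean-scale triple, which is the convention on which
the three parameterizations are directly comparable.

## Estimation

Parameters are estimated by full maximum likelihood with the exact analytic
gradient (shape-block entries involve `digamma`). Auxiliary constants are
estimated on the log scale, so positivity needs no constrained optimizer.

* Starting values: least squares of `log y` on `X` provides the varied
  block; the auxiliary starts at the method-of-moments value
  (`log(s²/ȳ)` for `β`, `log(ȳ²/s²)` for `α`) and the intercept is shifted
  to keep the implied mean intact. The shape/scale model starts from the
  better-fitting single-parameter model with the other block zeroed.
* Optimization: BFGS with the analytic gradient, followed by Newton
  refinement using the analytic Hessian (closed forms with `trigamma`
  terms; ridge-modified Cholesky when not positive definite). Near the
  optimum the objective decrease falls below the floating-point resolution
  of the log-likelihood, so the line search also accepts steps that shrink
  the gradient max-norm at machine-level objective change — without this
  the gradient stalls around `1e-5` on n = 1000 problems. Convergence
  requires gradient max-norm < 1e-6 and relative objective change < 1e-10;
  at most 500 iterations, with a Nelder–Mead restart if the line search
  fails far from a stationary point. Non-convergence is flagged on the
  result, never raised.
* Standard errors: inverse observed information (analytic negative
  Hessian at the optimum) — the conventional default of general-purpose ML
  routines.

### GLM-style standard errors for the scale model

The scale model's mean coefficients solve exactly the gamma GLM quasi-score
(the θ score is `Σ(y_i/β_i − α)x_i`, proportional to `Σ((y_i − μ_i)/μ_i)x_i`),
so in practice this model is fitted and reported as a GLM. GLM software
reports coefficient SEs from the quasi-likelihood Hessian
`X'diag(y/μ̂)X` scaled by the Pearson dispersion `Σ((y−μ̂)/μ̂)²/(n−k)`,
not from the joint ML observed information. Under a correctly specified
model the flavors agree asymptotically; under variance misspecification
they differ by several percent. `glm_mean_standard_errors` implements the
GLM convention, and the Monte Carlo harness uses it for the scale model
(observed information for the other parameterizations) so that each model
is summarized with the standard errors its users would actually see.

## Diagnostics

* **Normality of estimate distributions** — moment-based sample skewness
  and raw kurtosis (normal reference 3), with the D'Agostino transformed-z
  skewness test, the Anscombe–Glynn kurtosis test, and the joint chi²(2)
  omnibus, as implemented in `scipy.stats`. Requires n ≥ 8; constant input
  raises (the harness reports such entries as not applicable).
* **Modified Park test** — gamma-family log-link GLM of squared raw
  residuals on `log(ŷ)`; the slope estimates the power λ in
  `V(Y|x) ∝ E(Y|x)^λ`, with Wald tests against 0, 1, 2, 3. λ = 2 is the
  scale-model (classic gamma GLM) signature and λ = 1 the shape-model
  signature, so rejecting λ = 2 does not reject the gamma distribution —
  it may only reject where the covariates enter. An OLS-on-logs variant is
  available behind `method="ols"` for sensitivity.
* **Prediction criteria** — `R² = 1 − Var(y − ŷ)/Var(y)` with
  population-style (divide-by-n) variances in both numerator and
  denominator (the convention cancels in the ratio); R² is deliberately
  not clamped below zero, since a negative value is the signature of a
  regression function far from the true conditional mean. RMSE is
  `sqrt(mean((y − ŷ)²))`. Decile mean errors partition observations by the
  sample quantiles of `ŷ` at probabilities 0.1…0.9 with left-open /
  right-closed intervals; boundary ties go to the lower group, and if ties
  collapse groups, the empty slots inherit the merged group's mean and the
  collapse is flagged. The reported maximum is the *signed* decile error of
  largest magnitude. Decile errors need n ≥ 10; below that, R² and RMSE
  are still computed and the decile fields are not-applicable.
* **Joint Wald block test** — for the shape/scale model, `b'V_b⁻¹b` on a
  block's non-intercept coefficients against χ²(df); identifies which
  parameter the covariates act through, assuming the distribution is gamma.

## The synthetic data generator

`simulate_shape_dgp` draws `x ~ Uniform(0, 2)` i.i.d. and

    E(Y|x) = exp(2·x + 0.05·x² + 1),   β = e³,   α(x) = E(Y|x)/β,

with `y ~ Gamma(α(x), β)` — covariates act through the shape parameter, so
the conditional variance is `β·E(Y|x)` and the shape regression is the
correctly specified model while the scale regression (gamma GLM) is
misspecified. Defaults are the study conditions; `theta`, `log_beta`,
`x_range` and `n` are configurable for other scenarios. Note the shape
parameter spans roughly `e^−2` to `e^2.2` over the covariate range, so the
conditional distributions run from severely right-skewed to mildly skewed —
deliberately cost-like.

The generator emulates a clean, correctly specified world: a single smooth
predictor, no zeros or point mass at the origin, no censoring, truncation,
measurement error, or covariate collinearity beyond the built-in
`x`/`x²`/constant structure. Passing tests therefore demonstrate estimator
and diagnostic behaviour *under the stated conditions*, not robustness to
the messiness of real claims data.

## Monte Carlo harness

`run_monte_carlo` spawns one child stream per replicate from the master
seed via `numpy`'s `SeedSequence` (a counter-based scheme), so results are
bit-for-bit reproducible and order-independent. Each replicate draws a
dataset, fits the requested parameterizations, and records mean-scale
coefficients and SEs; summaries (mean, SD with n−1 denominator, mean SE,
skewness/kurtosis with p-values, joint normality p) are computed over
converged replicates only, with failures counted and the run aborted if
more than 1% fail (with this DGP the observed failure rate is zero).
Every summary carries its Monte Carlo standard error (`SD/√R` for means,
`SD·√(1/(2(R−1)))` for SDs) so comparisons can be tolerance-aware. The
study configuration is 10,000 replicates of n = 1,000 (≈2 minutes on one
CPU); replicate-level results are exposed as a long-format table and
written to CSV by the CLI.

## Numerical and design notes

* Non-positive outcomes (at or below the lower bound) raise immediately
  with the offending rows; silent dropping or imputation would change the
  estimand.
* The design matrix carries an explicit intercept column, ordered last.
* Overflow in `exp` during line search returns `+inf` objective, which the
  optimizer treats as a rejected step.
* The Wald block test refuses numerically singular block covariances
  (condition number > 1e12) and names near-collinearity as the likely
  cause.
* The shape/scale model doubles the parameter count for the same
  covariates; at n = 1,000 the split between blocks is weakly identified
  (block SEs several times larger than the single-model SEs) even though
  the implied mean coefficients remain tight. The joint block tests are
  the intended consumer of these fits.

## Known limitations

Only the natural-log link; no power-variance families beyond the three
parameterizations; no censoring, two-part/hurdle structure, or
robust/sandwich covariances (a natural extension); within-sample prediction
criteria only. The CLI's `table1` command and the acceptance script scale
the simulation by `--reps`/`--seed`; the reduced 2,000-replicate preset is
appropriate for desk checks with correspondingly wider Monte Carlo bands.
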