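# gammashape

Gamma regression for right-skewed outcomes — healthcare costs, lengths of
stay, waiting times — with covariates entering the **shape** parameter, the
**scale** parameter, or both, fitted by maximum likelihood with a log link.

## Why two (three) parameterizations?

A gamma outcome with shape `α` and scale `β` has `E(Y) = αβ` and
`V(Y) = αβ²`. Algebraically the variance is both `E(Y)²/α` and `β·E(Y)` —
indistinguishable for a single distribution, but not once covariates enter:

| model       | covariates in | conditional variance        |
|-------------|---------------|-----------------------------|
| scale       | `β(x)`        | `E(Y|x)² / α` (∝ mean²)     |
| shape       | `α(x)`        | `β · E(Y|x)` (∝ mean)       |
| shape/scale | both          | neither power holds globally |

The scale model is the classical gamma GLM. The shape model shares the same
log-link regression function `E(Y|x) = exp(θ'x)` but imposes variance
proportional to the mean. When the data follow one specification and the
other is fitted, coefficient sampling distributions become skewed, less
efficient, and their model-based standard errors understate the true
spread — and a rejected Modified Park test of `V ∝ mean²` does **not** mean
the outcome is not gamma; the covariates may simply act through the shape
parameter. The package provides the three fits, a Monte Carlo harness that
quantifies the cost of misspecification, and the diagnostics (Modified Park
test, joint Wald block tests, normality tests of estimate distributions,
R²/RMSE/decile-error prediction criteria) needed to choose among them.

See `docs/methods.md` for the estimation details and conventions.

## Worked example

Simulate 5,000 cost-like observations whose conditional mean is
`exp(2x + 0.05x² + 1)` with constant scale `β = e³` (so the variance is
proportional to the mean and the *shape* model is correctly specified),
then fit and diagnose:

```sh
gammashape simulate --n 5000 --seed 42 --out sim
gammashape fit --input sim/simulated.csv --outcome y --covariates x,x2 \
    --model shape --out fitout
```

```text
gamma shape model (n=5000, loglik=-17105.4231, converged=True)
parameter             estimate    std. error
shape:x               1.981467      0.074626
shape:x2              0.063128      0.031221
shape:const          -1.998472      0.037882
log_beta              2.989028      0.023688
```

The shape-block coefficients are effects on `log α`; on the conditional
mean's log scale the intercept is `shape:const + log_beta ≈ 0.99`, so the
fit recovers the generating values (2, 0.05, 1) and `log β = 3` within one
standard error. Comparing parameterizations on the same data:

```sh
gammashape diagnose --input sim/simulated.csv --outcome y --covariates x,x2 --out diag
```

```text
scale: R2=0.7171  RMSE=28.5238  max decile error=5.3060  Park lambda=0.966
shape: R2=0.7189  RMSE=28.4331  max decile error=-1.5457  Park lambda=0.962
```

Both models estimate the mean well here, but the Modified Park power
`λ ≈ 1` (variance proportional to the mean, not its square) identifies the
shape specification, and the shape model's largest decile-mean residual is
about a third of the scale model's.

The estimator comparison itself — 10,000 replicates of n = 1,000, both
models fitted to every replicate, sampling-distribution summaries with
Monte Carlo standard errors — runs in about two minutes:

```sh
gammashape table1 --reps 10000 --n 1000 --seed 11 --out mc
```

Under this process the misspecified scale model's coefficient on x² is
biased by roughly 25–30% and its mean estimated standard errors fall 20–40%
below the empirical sampling SDs, while the correctly specified shape model
is unbiased with SEs matching the SDs and roughly half the sampling spread.

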