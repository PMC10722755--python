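"""Specification diagnostics and within-sample prediction criteria.

Covers three needs when comparing gamma regression parameterizations on
right-skewed outcomes:

* normality checks for Monte Carlo estimate distributions (moment-based
  skewness/kurtosis with the D'Agostino-type transformed z tests and the
  joint omnibus chi-square);
* the Modified Park test, which estimates the power ``lambda`` in
  ``Var(Y|x) ∝ E(Y|x)**lambda`` from a log-link GLM of squared residuals on
  log predictions — ``lambda = 2`` is the classic gamma-family (scale model)
  signature, ``lambda = 1`` the shape-model signature;
* prediction criteria: R-squared as one minus the ratio of residual to
  total variance, root mean squared error, and mean residuals by decile of
  predicted values with the largest-magnitude signed decile error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "NormalitySummary",
    "ParkTestResult",
    "PredictionMetrics",
    "skewness_kurtosis_test",
    "modified_park_test",
    "prediction_metrics",
    "decile_mean_errors",
]


@dataclass(frozen=True)
class NormalitySummary:
    skewness: float
    kurtosis: float  # raw fourth standardized moment; normal reference is 3
    p_skewness: float
    p_kurtosis: float
    p_joint: float


@dataclass(frozen=True)
class ParkTestResult:
    lambda_hat: float
    se_lambda: float
    p_vs: dict[int, float]  # Wald p-values for lambda in {0, 1, 2, 3}


@dataclass(frozen=True)
class PredictionMetrics:
    r_squared: float
    rmse: float
    decile_mean_errors: np.ndarray
    decile_counts: np.ndarray
    max_decile_error: float
    collapsed_deciles: bool


def skewness_kurtosis_test(samples) -> NormalitySummary:
    """Sample skewness/kurtosis with transformed z tests and joint omnibus.

    Skewness is the third standardized sample moment and kurtosis the raw
    fourth (normal = 3).  The individual p-values use the D'Agostino
    skewness and Anscombe–Glynn kurtosis transformations; the joint test is
    the chi-square(2) omnibus combining both z statistics.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise ValueError("at least 8 observations are required")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; standardized moments undefined")
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x, fisher=False))
    p_skew = float(stats.skewtest(x).pvalue)
    p_kurt = float(stats.kurtosistest(x).pvalue)
    p_joint = float(stats.normaltest(x).pvalue)
    return NormalitySummary(skew, kurt, p_skew, p_kurt, p_joint)


def modified_park_test(y, yhat, method: str = "glm") -> ParkTestResult:
    """Modified Park test of the variance-power specification.

    Regresses squared raw residuals ``(y - yhat)**2`` on ``log(yhat)``.  With
    ``method="glm"`` (default) a gamma-family log-link GLM is used; with
    ``method="ols"`` ordinary least squares of ``log`` squared residuals on
    ``log(yhat)`` is used as a sensitivity variant.  Reports Wald tests of
    the power against 0 (homoskedastic), 1 (variance ∝ mean, gamma shape
    model), 2 (variance ∝ mean², gamma scale model) and 3.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if np.any(yhat <= 0):
        raise ValueError("predicted means must be strictly positive")
    r2 = (y - yhat) ** 2
    if np.any(r2 == 0):
        raise ValueError("zero residuals: squared-residual regression undefined")
    exog = np.column_stack([np.log(yhat), np.ones_like(yhat)])
    if method == "glm":
        model = sm.GLM(r2, exog, family=sm.families.Gamma(sm.families.links.Log()))
        res = model.fit()
    elif method == "ols":
        res = sm.OLS(np.log(r2), exog).fit()
    else:
        raise ValueError("method must be 'glm' or 'ols'")
    lam = float(res.params[0])
    se = float(res.bse[0])
    p_vs = {
        k: float(2.0 * stats.norm.sf(abs((lam - k) / se))) for k in (0, 1, 2, 3)
    }
    return ParkTestResult(lambda_hat=lam, se_lambda=se, p_vs=p_vs)


def decile_mean_errors(y, yhat):
    """Mean residuals ``y - yhat`` within deciles of the predicted values.

    Groups are formed from sample quantiles of ``yhat`` at probabilities
    0.1..0.9 with left-open/right-closed intervals; boundary ties fall in
    the lower group.  If ties collapse groups, each empty decile slot
    inherits the mean of the group it merged into and the collapse is
    flagged.  Returns ``(errors, counts, max_error, collapsed)`` where
    ``max_error`` is the signed decile error of largest magnitude.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if y.size < 10:
        raise ValueError("at least 10 observations are required for deciles")
    resid = y - yhat
    cuts = np.quantile(yhat, np.arange(1, 10) / 10.0)
    idx = np.searchsorted(cuts, yhat, side="left")
    counts = np.bincount(idx, minlength=10).astype(int)
    sums = np.bincount(idx, weights=resid, minlength=10)
    errors = np.full(10, np.nan)
    nonempty = counts > 0
    errors[nonempty] = sums[nonempty] / counts[nonempty]
    collapsed = bool(np.any(~nonempty))
    # empty slots arise from tied quantiles; they merged into the nearest
    # lower occupied slot
    last = errors[0]
    for j in range(10):
        if nonempty[j]:
            last = errors[j]
        else:
            errors[j] = last
    occupied = errors[nonempty]
    max_error = float(occupied[np.argmax(np.abs(occupied))])
    return errors, counts, max_error, collapsed


def prediction_metrics(y, yhat) -> PredictionMetrics:
    """R-squared, RMSE and decile mean errors for predicted means.

    ``r_squared = 1 - Var(y - yhat)/Var(y)`` with population (divide-by-n)
    variances; it is not clamped and can be negative when the regression
    function misses the true conditional expectation badly.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("outcome variance is zero; R-squared undefined")
    resid = y - yhat
    r_squared = 1.0 - float(np.var(resid)) / var_y
    rmse = float(np.sqrt(np.mean(resid**2)))
    if y.size >= 10:
        errors, counts, max_error, collapsed = decile_mean_errors(y, yhat)
    else:  # decile errors need at least 10 observations
        errors = np.full(10, np.nan)
        counts = np.zeros(10, dtype=int)
        max_error, collapsed = float("nan"), True
    return PredictionMetrics(
        r_squared=r_squared,
        rmse=rmse,
        decile_mean_errors=errors,
        decile_counts=counts,
        max_decile_error=max_error,
        collapsed_deciles=collapsed,
    )
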