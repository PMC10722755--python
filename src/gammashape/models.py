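"""Gamma regression with covariates in the shape parameter, the scale
parameter, or both.

The gamma density with shape ``alpha`` and scale ``beta`` has mean
``alpha * beta`` and variance ``alpha * beta**2``.  When covariates enter
through the scale parameter (``alpha`` constant) the conditional variance is
proportional to the squared conditional mean — the familiar gamma GLM
variance function.  When they enter through the shape parameter (``beta``
constant) the variance is instead directly proportional to the mean.  The
two specifications share the same log-link regression function yet impose
different mean–variance relationships across the covariate range, so fitting
the wrong one yields inconsistent standard errors and finite-sample
coefficient bias.  A third parameterization lets covariates move both
parameters and nests the other two.

All models are fitted by maximum likelihood with an analytic gradient;
standard errors come from the inverse observed information (negative Hessian
of the log-likelihood at the optimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import linalg, optimize, special, stats

__all__ = [
    "GammaParams",
    "ModelSpec",
    "FitResult",
    "TestResult",
    "gamma_logpdf",
    "gamma_moments",
    "negative_loglik",
    "fit_gamma_regression",
    "predict_mean",
    "wald_joint_test",
]

Parameterization = Literal["scale", "shape", "shape_scale"]
_PARAMETERIZATIONS = ("scale", "shape", "shape_scale")


@dataclass(frozen=True)
class GammaParams:
    """A single gamma distribution: shape ``alpha``, scale ``beta`` and an
    optional greatest lower bound ``lower_bound`` shifting the support to
    ``(lower_bound, inf)``."""

    alpha: float
    beta: float
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"shape parameter must be positive, got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"scale parameter must be positive, got {self.beta}")
        if not np.isfinite(self.lower_bound):
            raise ValueError("lower_bound must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """Which gamma parameter the covariates enter, and the design columns.

    ``covariate_names`` lists the design-matrix columns in order, with the
    explicit intercept column last (e.g. ``("x", "x2", "const")``).  The link
    for the varied parameter(s) is the natural log.
    """

    parameterization: Parameterization
    covariate_names: tuple[str, ...]
    link: str = "log"

    def __post_init__(self) -> None:
        if self.parameterization not in _PARAMETERIZATIONS:
            raise ValueError(
                f"parameterization must be one of {_PARAMETERIZATIONS}, "
                f"got {self.parameterization!r}"
            )
        if len(self.covariate_names) < 1:
            raise ValueError("at least the intercept column is required")
        if self.link != "log":
            raise ValueError("only the natural-log link is supported")
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def n_parameters(self) -> int:
        k = self.n_covariates
        return 2 * k if self.parameterization == "shape_scale" else k + 1

    def parameter_names(self) -> tuple[str, ...]:
        k = self.covariate_names
        if self.parameterization == "shape":
            return tuple(f"shape:{c}" for c in k) + ("log_beta",)
        if self.parameterization == "scale":
            return tuple(f"scale:{c}" for c in k) + ("log_alpha",)
        return tuple(f"shape:{c}" for c in k) + tuple(f"scale:{c}" for c in k)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a gamma regression.

    ``theta_shape`` / ``theta_scale`` are the coefficient vectors on the log
    of the varied parameter(s); the one not varied is empty and its log value
    is held in ``aux_log_constant`` (log beta for the shape model, log alpha
    for the scale model; None for shape_scale).
    """

    spec: ModelSpec
    theta_shape: np.ndarray
    theta_scale: np.ndarray
    aux_log_constant: float | None
    loglik: float
    covariance: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    n_iterations: int
    n_observations: int
    lower_bound: float = 0.0
    gradient_max_norm: float = float("nan")

    @property
    def params(self) -> np.ndarray:
        """Packed parameter vector in the internal optimizer order."""
        if self.spec.parameterization == "shape":
            return np.append(self.theta_shape, self.aux_log_constant)
        if self.spec.parameterization == "scale":
            return np.append(self.theta_scale, self.aux_log_constant)
        return np.concatenate([self.theta_shape, self.theta_scale])

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients of the varied parameter(s) only (no auxiliary)."""
        if self.spec.parameterization == "shape":
            return self.theta_shape
        if self.spec.parameterization == "scale":
            return self.theta_scale
        return np.concatenate([self.theta_shape, self.theta_scale])

    def _mean_transform(self) -> np.ndarray:
        """Linear map from packed parameters to log-mean coefficients."""
        k = self.spec.n_covariates
        if self.spec.parameterization == "shape_scale":
            return np.hstack([np.eye(k), np.eye(k)])
        M = np.hstack([np.eye(k), np.zeros((k, 1))])
        M[-1, -1] = 1.0  # log mean = theta'x + aux, intercept last
        return M

    @property
    def mean_coefficients(self) -> np.ndarray:
        """Coefficients on the log conditional mean, GLM-style.

        All parameterizations here share the regression function
        ``E(Y|x) = L + exp(b'x)``; the slopes equal the varied block's and the
        intercept is the varied block's intercept plus the auxiliary log
        constant (for shape_scale, the sum of the two blocks).
        """
        return self._mean_transform() @ self.params

    @property
    def mean_standard_errors(self) -> np.ndarray:
        """Delta-method standard errors for :attr:`mean_coefficients`."""
        M = self._mean_transform()
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(M @ self.covariance @ M.T))

    def to_dict(self) -> dict:
        return {
            "parameterization": self.spec.parameterization,
            "covariate_names": list(self.spec.covariate_names),
            "parameter_names": list(self.spec.parameter_names()),
            "theta_shape": self.theta_shape.tolist(),
            "theta_scale": self.theta_scale.tolist(),
            "aux_log_constant": self.aux_log_constant,
            "mean_coefficients": self.mean_coefficients.tolist(),
            "mean_standard_errors": self.mean_standard_errors.tolist(),
            "loglik": self.loglik,
            "standard_errors": self.standard_errors.tolist(),
            "covariance": self.covariance.tolist(),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "n_observations": int(self.n_observations),
            "lower_bound": self.lower_bound,
            "gradient_max_norm": self.gradient_max_norm,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def gamma_logpdf(y, params: GammaParams):
    """Log-density of the (possibly shifted) gamma distribution.

    Supports scalars or arrays; every value must exceed ``params.lower_bound``.
    """
    y = np.asarray(y, dtype=float)
    z = y - params.lower_bound
    if np.any(z <= 0):
        raise ValueError(
            f"outcome values must exceed the lower bound {params.lower_bound}"
        )
    a, b = params.alpha, params.beta
    out = (a - 1.0) * np.log(z) - z / b - special.gammaln(a) - a * np.log(b)
    return out if out.ndim else float(out)


def gamma_moments(params: GammaParams) -> tuple[float, float]:
    """Mean and variance: ``L + alpha*beta`` and ``alpha*beta**2``."""
    mean = params.lower_bound + params.alpha * params.beta
    variance = params.alpha * params.beta**2
    return mean, variance


def _validate_design(X: np.ndarray, y: np.ndarray, lower_bound: float) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains NaN or infinite entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome vector contains NaN or infinite entries")
    if np.any(y <= lower_bound):
        bad = np.nonzero(y <= lower_bound)[0]
        raise ValueError(
            f"outcome must be strictly greater than {lower_bound}; offending "
            f"rows (0-based): {bad[:20].tolist()}"
        )
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")


def negative_loglik(
    params_vector: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    lower_bound: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Negative gamma log-likelihood and its exact analytic gradient.

    Packing: ``shape`` -> (theta_shape, log beta); ``scale`` ->
    (theta_scale, log alpha); ``shape_scale`` -> (theta_shape, theta_scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(params_vector, dtype=float)
    _validate_design(X, y, lower_bound)
    k = X.shape[1]
    if k != spec.n_covariates:
        raise ValueError("design column count does not match the model spec")
    if v.shape[0] != spec.n_parameters:
        raise ValueError(
            f"expected {spec.n_parameters} packed parameters, got {v.shape[0]}"
        )

    z = y - lower_bound
    logz = np.log(z)
    grad = np.empty_like(v)

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if spec.parameterization == "shape":
            theta, log_b = v[:k], v[k]
            eta_a = X @ theta
            a = np.exp(eta_a)
            b = np.exp(log_b)
            ll = (a - 1.0) * logz - z / b - special.gammaln(a) - a * log_b
            value = -np.sum(ll)
            if not np.isfinite(value):
                return np.inf, np.zeros_like(v)
            w = a * (logz - special.digamma(a) - log_b)
            grad[:k] = -(X.T @ w)
            grad[k] = -np.sum(z / b - a)
        elif spec.parameterization == "scale":
            theta, log_a = v[:k], v[k]
            eta_b = X @ theta
            b = np.exp(eta_b)
            a = np.exp(log_a)
            ll = (a - 1.0) * logz - z / b - special.gammaln(a) - a * eta_b
            value = -np.sum(ll)
            if not np.isfinite(value):
                return np.inf, np.zeros_like(v)
            w = z / b - a
            grad[:k] = -(X.T @ w)
            grad[k] = -a * np.sum(logz - special.digamma(a) - eta_b)
        else:  # shape_scale
            th_a, th_b = v[:k], v[k:]
            eta_a = X @ th_a
            eta_b = X @ th_b
            a = np.exp(eta_a)
            b = np.exp(eta_b)
            ll = (a - 1.0) * logz - z / b - special.gammaln(a) - a * eta_b
            value = -np.sum(ll)
            if not np.isfinite(value):
                return np.inf, np.zeros_like(v)
            wa = a * (logz - special.digamma(a) - eta_b)
            wb = z / b - a
            grad[:k] = -(X.T @ wa)
            grad[k:] = -(X.T @ wb)

    if not np.all(np.isfinite(grad)):
        return np.inf, np.zeros_like(v)
    return float(value), grad


def negative_loglik_hessian(
    params_vector: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    lower_bound: float = 0.0,
) -> np.ndarray:
    """Analytic Hessian of the negative log-likelihood (observed information)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    v = np.asarray(params_vector, dtype=float)
    k = X.shape[1]
    z = y - lower_bound
    logz = np.log(z)
    H = np.empty((v.size, v.size))

    with np.errstate(over="ignore", invalid="ignore"):
        if spec.parameterization == "shape":
            theta, log_b = v[:k], v[k]
            a = np.exp(X @ theta)
            b = np.exp(log_b)
            w = a * (logz - special.digamma(a) - log_b)
            d = w - a**2 * special.polygamma(1, a)
            H[:k, :k] = -(X.T * d) @ X
            H[:k, k] = H[k, :k] = X.T @ a
            H[k, k] = np.sum(z) / b
        elif spec.parameterization == "scale":
            theta, log_a = v[:k], v[k]
            eta_b = X @ theta
            b = np.exp(eta_b)
            a = np.exp(log_a)
            H[:k, :k] = (X.T * (z / b)) @ X
            H[:k, k] = H[k, :k] = a * np.sum(X, axis=0)
            s = np.sum(logz - special.digamma(a) - eta_b)
            H[k, k] = -a * s + a**2 * special.polygamma(1, a) * y.size
        else:  # shape_scale
            th_a, th_b = v[:k], v[k:]
            eta_b = X @ th_b
            a = np.exp(X @ th_a)
            b = np.exp(eta_b)
            wa = a * (logz - special.digamma(a) - eta_b)
            da = wa - a**2 * special.polygamma(1, a)
            H[:k, :k] = -(X.T * da) @ X
            Hab = (X.T * a) @ X
            H[:k, k:] = Hab
            H[k:, :k] = Hab.T
            H[k:, k:] = (X.T * (z / b)) @ X
    return 0.5 * (H + H.T)


_GTOL = 1e-6
_FTOL = 1e-10


def _newton_polish(fun_grad, hess, x: np.ndarray, max_iter: int = 50):
    """Newton refinement with backtracking (and a ridge fallback when the
    Hessian is not positive definite) until the gradient max-norm falls below
    ``_GTOL`` and the relative objective change below ``_FTOL``."""
    f, g = fun_grad(x)
    n_iter = 0
    for _ in range(max_iter):
        if np.max(np.abs(g)) < _GTOL:
            break
        H = hess(x)
        step = None
        ridge = 0.0
        scale = np.max(np.abs(np.diag(H))) or 1.0
        for _ in range(12):
            try:
                c, low = linalg.cho_factor(H + ridge * scale * np.eye(x.size))
                step = linalg.cho_solve((c, low), -g)
                break
            except np.linalg.LinAlgError:
                ridge = max(2.0 * ridge, 1e-10)
        if step is None or not np.all(np.isfinite(step)) or step @ g >= 0:
            step = -g / scale
        t = 1.0
        improved = False
        # near the optimum the predicted decrease falls below the floating-
        # point resolution of f; accept a step on gradient-norm descent then
        f_slack = 4.0 * np.finfo(float).eps * max(1.0, abs(f))
        for _ in range(50):
            f_new, g_new = fun_grad(x + t * step)
            if np.isfinite(f_new) and (
                f_new <= f + 1e-4 * t * (g @ step)
                or (f_new <= f + f_slack
                    and np.max(np.abs(g_new)) < np.max(np.abs(g)))
            ):
                improved = True
                break
            t *= 0.5
        n_iter += 1
        if not improved:
            break
        rel_change = abs(f - f_new) / max(1.0, abs(f))
        x, f, g = x + t * step, f_new, g_new
        if rel_change < _FTOL and np.max(np.abs(g)) < _GTOL:
            break
    return x, f, g, n_iter


def _starting_values(X, y, spec: ModelSpec, lower_bound: float) -> np.ndarray:
    z = y - lower_bound
    logz = np.log(z)
    b0, *_ = np.linalg.lstsq(X, logz, rcond=None)
    zbar = float(np.mean(z))
    s2 = float(np.var(z, ddof=1)) if z.size > 1 else zbar**2
    s2 = max(s2, 1e-12)
    if spec.parameterization == "shape":
        aux = float(np.log(max(s2 / zbar, 1e-8)))  # MoM for beta
    else:
        aux = float(np.log(max(zbar**2 / s2, 1e-8)))  # MoM for alpha
    theta = b0.copy()
    theta[-1] -= aux  # log mean = theta'x + aux; intercept is the last column
    return np.append(theta, aux)


def fit_gamma_regression(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    lower_bound: float = 0.0,
    max_iter: int = 500,
) -> FitResult:
    """Fit a gamma regression by maximum likelihood.

    Quasi-Newton (BFGS) with the analytic gradient, followed by Newton
    refinement; a Nelder–Mead restart is attempted if the line search fails
    far from a stationary point.  Standard errors come from the inverse
    observed information.  Non-convergence is reported through
    ``converged=False``, never an exception.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_design(X, y, lower_bound)
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if y.size <= spec.n_parameters:
        raise ValueError("need more observations than parameters")

    def fun_grad(v):
        return negative_loglik(v, X, y, spec, lower_bound)

    def hess(v):
        return negative_loglik_hessian(v, X, y, spec, lower_bound)

    if spec.parameterization == "shape_scale":
        shape_fit = fit_gamma_regression(
            X, y, ModelSpec("shape", spec.covariate_names), lower_bound, max_iter
        )
        scale_fit = fit_gamma_regression(
            X, y, ModelSpec("scale", spec.covariate_names), lower_bound, max_iter
        )
        best = shape_fit if shape_fit.loglik >= scale_fit.loglik else scale_fit
        other = np.zeros(k)
        other[-1] = best.aux_log_constant
        if best.spec.parameterization == "shape":
            x0 = np.concatenate([best.theta_shape, other])
        else:
            x0 = np.concatenate([other, best.theta_scale])
    else:
        x0 = _starting_values(X, y, spec, lower_bound)

    res = optimize.minimize(
        fun_grad, x0, jac=True, method="BFGS",
        options={"gtol": _GTOL, "maxiter": max_iter},
    )
    x_best, f_best = res.x, res.fun
    n_iter = res.nit
    if not np.isfinite(f_best) or np.max(np.abs(res.jac)) > 1e-2:
        # line search failed far from a stationary point: derivative-free restart
        nm = optimize.minimize(
            lambda v: fun_grad(v)[0], x0, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if np.isfinite(nm.fun) and nm.fun < f_best:
            x_best, f_best = nm.x, nm.fun
            n_iter += nm.nit

    x_best, f_best, g_best, polish_iters = _newton_polish(fun_grad, hess, x_best)
    n_iter += polish_iters
    gmax = float(np.max(np.abs(g_best)))
    converged = bool(np.isfinite(f_best) and gmax < _GTOL)

    H = hess(x_best)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        converged = False
    cov = 0.5 * (cov + cov.T)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(cov))
    if np.any(~np.isfinite(se)):
        converged = False

    if spec.parameterization == "shape":
        theta_shape, theta_scale = x_best[:k], np.empty(0)
        aux = float(x_best[k])
    elif spec.parameterization == "scale":
        theta_shape, theta_scale = np.empty(0), x_best[:k]
        aux = float(x_best[k])
    else:
        theta_shape, theta_scale = x_best[:k], x_best[k:]
        aux = None

    return FitResult(
        spec=spec,
        theta_shape=theta_shape,
        theta_scale=theta_scale,
        aux_log_constant=aux,
        loglik=float(-f_best),
        covariance=cov,
        standard_errors=se,
        converged=converged,
        n_iterations=int(n_iter),
        n_observations=int(y.size),
        lower_bound=lower_bound,
        gradient_max_norm=gmax,
    )


def glm_mean_standard_errors(fit: FitResult, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """GLM-conventional standard errors for a scale-parameterization fit.

    The scale model's mean coefficients solve exactly the gamma GLM (log
    link) quasi-score, and GLM practice reports standard errors from the
    observed Hessian of the quasi-log-likelihood, ``X' diag(y/mu) X``, scaled
    by the Pearson dispersion ``phi = sum((y - mu)^2 / mu^2) / (n - k)``.
    Under misspecification these differ from the observed-information SEs of
    the joint MLE.
    """
    if fit.spec.parameterization != "scale":
        raise ValueError("GLM-style standard errors apply to the scale model")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = np.exp(X @ fit.mean_coefficients)
    n, k = X.shape
    phi = float(np.sum((y - mu) ** 2 / mu**2) / (n - k))
    H = (X.T * (y / mu)) @ X
    return np.sqrt(np.diag(np.linalg.inv(H)) * phi)


def predict_mean(fit: FitResult, X: np.ndarray) -> np.ndarray:
    """Conditional mean ``L + alpha(x) * beta(x)`` at each design row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fit.spec.n_covariates:
        raise ValueError(
            f"design must have {fit.spec.n_covariates} columns, got {X.shape}"
        )
    p = fit.spec.parameterization
    if p == "shape":
        eta = X @ fit.theta_shape + fit.aux_log_constant
    elif p == "scale":
        eta = X @ fit.theta_scale + fit.aux_log_constant
    else:
        eta = X @ fit.theta_shape + X @ fit.theta_scale
    return fit.lower_bound + np.exp(eta)


def wald_joint_test(fit: FitResult, block: Literal["shape", "scale"]) -> TestResult:
    """Joint Wald chi-square test that a block's non-intercept coefficients
    are all zero, for a shape/scale fit.

    Used to determine which gamma parameter the covariates act through: a
    rejected shape block with a quiet scale block points to the shape
    parameterization, and vice versa.
    """
    if fit.spec.parameterization != "shape_scale":
        raise ValueError("joint block test requires a shape_scale fit")
    if block not in ("shape", "scale"):
        raise ValueError("block must be 'shape' or 'scale'")
    k = fit.spec.n_covariates
    if k < 2:
        raise ValueError("no non-intercept coefficients in an intercept-only model")
    # packing: [theta_shape (k), theta_scale (k)], intercept last in each block
    offset = 0 if block == "shape" else k
    idx = np.arange(offset, offset + k - 1)
    b = fit.params[idx]
    V = fit.covariance[np.ix_(idx, idx)]
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "block covariance is numerically singular (near-collinear covariates)"
        )
    stat = float(b @ np.linalg.solve(V, b))
    df = idx.size
    p = float(stats.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p)
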