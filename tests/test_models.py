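"""Likelihood, gradient, fitting, prediction and Wald tests."""

import numpy as np
import pytest
import statsmodels.api as sm

from gammashape import (
    ModelSpec,
    fit_gamma_regression,
    gamma_logpdf,
    GammaParams,
    negative_loglik,
    predict_mean,
    simulate_shape_dgp,
    wald_joint_test,
)
from gammashape.models import negative_loglik_hessian

COVS = ("x", "x2", "const")


def _random_point(spec, rng):
    """Admissible packed parameter point keeping alpha, beta in sane ranges."""
    v = rng.uniform(-0.4, 0.4, size=spec.n_parameters)
    v[spec.n_covariates - 1] += 1.0  # varied-block intercept
    v[-1] += 0.5
    return v


class TestNegativeLoglik:
    def test_single_observation_reduces_to_density(self):
        spec = ModelSpec("shape", ("const",))
        y = np.array([1.7])
        X = np.ones((1, 1))
        val, _ = negative_loglik(np.zeros(2), X, y, spec)
        assert val == pytest.approx(-gamma_logpdf(1.7, GammaParams(1.0, 1.0)))

    def test_shape_scale_nests_shape(self, dataset_n1000):
        ds = dataset_n1000
        theta = np.array([0.3, 0.02, 0.9])
        c = 0.7
        v_shape = np.append(theta, c)
        v_both = np.concatenate([theta, [0.0, 0.0, c]])
        val_s, _ = negative_loglik(v_shape, ds.design, ds.y,
                                   ModelSpec("shape", COVS))
        val_b, _ = negative_loglik(v_both, ds.design, ds.y,
                                   ModelSpec("shape_scale", COVS))
        assert val_b == pytest.approx(val_s, rel=1e-12)

    def test_rejects_nonpositive_outcomes_and_bad_design(self):
        spec = ModelSpec("shape", ("const",))
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="strictly greater"):
            negative_loglik(np.zeros(2), X, np.array([1.0, 0.0, 2.0]), spec)
        with pytest.raises(ValueError, match="NaN or infinite"):
            negative_loglik(
                np.zeros(2), np.array([[1.0], [np.nan], [1.0]]),
                np.array([1.0, 1.0, 2.0]), spec,
            )

    def test_gradient_matches_central_differences(self, any_spec, rng):
        """Analytic gradient vs numeric differentiation at random admissible
        points (relative error < 1e-6 on the gradient max-norm scale)."""
        ds = simulate_shape_dgp(60, seed=rng.integers(2**31))
        h = 1e-6
        for _ in range(12):
            v = _random_point(any_spec, rng)
            _, g = negative_loglik(v, ds.design, ds.y, any_spec)
            num = np.empty_like(g)
            for j in range(v.size):
                e = np.zeros_like(v)
                e[j] = h
                fp, _ = negative_loglik(v + e, ds.design, ds.y, any_spec)
                fm, _ = negative_loglik(v - e, ds.design, ds.y, any_spec)
                num[j] = (fp - fm) / (2 * h)
            scale = max(1.0, np.max(np.abs(g)))
            assert np.max(np.abs(g - num)) / scale < 1e-6

    def test_hessian_matches_gradient_differences(self, any_spec, rng):
        ds = simulate_shape_dgp(60, seed=rng.integers(2**31))
        v = _random_point(any_spec, rng)
        H = negative_loglik_hessian(v, ds.design, ds.y, any_spec)
        h = 1e-6
        num = np.empty_like(H)
        for j in range(v.size):
            e = np.zeros_like(v)
            e[j] = h
            _, gp = negative_loglik(v + e, ds.design, ds.y, any_spec)
            _, gm = negative_loglik(v - e, ds.design, ds.y, any_spec)
            num[:, j] = (gp - gm) / (2 * h)
        scale = max(1.0, np.max(np.abs(H)))
        assert np.max(np.abs(H - num)) / scale < 1e-5


class TestFit:
    def test_intercept_only_mle_reproduces_sample_mean(self, rng):
        """First-order condition: fitted mean alpha*beta equals ybar."""
        y = rng.gamma(3.0, 2.0, size=200)
        X = np.ones((200, 1))
        for p in ("shape", "scale"):
            fit = fit_gamma_regression(X, y, ModelSpec(p, ("const",)))
            fitted = float(np.exp(fit.mean_coefficients[0]))
            assert fit.converged
            assert fitted == pytest.approx(np.mean(y), abs=1e-8)

    def test_scale_model_equals_gamma_glm(self, dataset_n1000):
        """The scale model's mean coefficients solve the gamma GLM quasi-
        score: slopes and intercept match statsmodels' IRLS fit to 1e-6, and
        the GLM intercept decomposes into scale-block intercept + log alpha."""
        ds = dataset_n1000
        fit = fit_gamma_regression(ds.design, ds.y, ModelSpec("scale", COVS))
        glm = sm.GLM(
            ds.y, ds.design,
            family=sm.families.Gamma(sm.families.links.Log()),
        ).fit(tol=1e-12)
        np.testing.assert_allclose(fit.mean_coefficients, glm.params, atol=1e-6)
        assert fit.theta_scale[-1] + fit.aux_log_constant == pytest.approx(
            glm.params[-1], abs=1e-6
        )

    def test_nesting_loglik_inequality(self, dataset_n1000):
        ds = dataset_n1000
        lls = {
            p: fit_gamma_regression(ds.design, ds.y, ModelSpec(p, COVS)).loglik
            for p in ("shape", "scale", "shape_scale")
        }
        assert lls["shape_scale"] >= lls["shape"] - 1e-6
        assert lls["shape_scale"] >= lls["scale"] - 1e-6

    def test_shape_model_recovers_dgp_parameters(self):
        """At n=100,000 the correctly specified shape model recovers the
        generating values (2, 0.05, 1) and log beta = 3 within 3 SE."""
        ds = simulate_shape_dgp(100_000, seed=2718281)
        fit = fit_gamma_regression(ds.design, ds.y, ModelSpec("shape", COVS))
        assert fit.converged
        truth = np.array([2.0, 0.05, 1.0])
        err = np.abs(fit.mean_coefficients - truth)
        assert np.all(err < 3.0 * fit.mean_standard_errors)
        aux_se = fit.standard_errors[-1]
        assert abs(fit.aux_log_constant - 3.0) < 3.0 * aux_se

    def test_rank_deficient_design_rejected(self, rng):
        y = rng.gamma(2.0, 1.0, 50) + 0.01
        x = rng.uniform(0, 1, 50)
        X = np.column_stack([x, 2 * x, np.ones(50)])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_gamma_regression(X, y, ModelSpec("shape", COVS))

    def test_covariance_symmetric_psd_and_se_consistent(self, dataset_n1000):
        ds = dataset_n1000
        fit = fit_gamma_regression(ds.design, ds.y, ModelSpec("shape", COVS))
        assert fit.converged
        np.testing.assert_allclose(fit.covariance, fit.covariance.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.covariance) > -1e-10)
        np.testing.assert_allclose(
            fit.standard_errors, np.sqrt(np.diag(fit.covariance))
        )
        assert np.isfinite(fit.loglik)


class TestPredictMean:
    def test_intercept_only_predicts_ybar(self, rng):
        y = rng.gamma(2.0, 5.0, 100)
        X = np.ones((100, 1))
        fit = fit_gamma_regression(X, y, ModelSpec("shape", ("const",)))
        np.testing.assert_allclose(predict_mean(fit, X), np.mean(y), atol=1e-7)

    def test_shape_and_scale_predictions_differ_under_heteroskedasticity(
        self, dataset_n1000
    ):
        ds = dataset_n1000
        f1 = fit_gamma_regression(ds.design, ds.y, ModelSpec("shape", COVS))
        f2 = fit_gamma_regression(ds.design, ds.y, ModelSpec("scale", COVS))
        p1, p2 = predict_mean(f1, ds.design), predict_mean(f2, ds.design)
        assert np.all(p1 > 0) and np.all(p2 > 0)
        assert np.max(np.abs(p1 - p2)) > 1e-3

    def test_dimension_mismatch(self, dataset_n1000):
        ds = dataset_n1000
        fit = fit_gamma_regression(ds.design, ds.y, ModelSpec("shape", COVS))
        with pytest.raises(ValueError, match="columns"):
            predict_mean(fit, ds.design[:, :2])


class TestWaldJointTest:
    def test_single_covariate_block_is_squared_z(self, rng):
        ds = simulate_shape_dgp(400, seed=99)
        X = np.column_stack([ds.x, np.ones(400)])
        fit = fit_gamma_regression(X, ds.y, ModelSpec("shape_scale", ("x", "const")))
        t = wald_joint_test(fit, "shape")
        z2 = (fit.params[0] / fit.standard_errors[0]) ** 2
        assert t.df == 1
        assert t.statistic == pytest.approx(z2, abs=1e-10)

    def test_zero_block_gives_zero_statistic(self, dataset_n1000):
        ds = dataset_n1000
        fit = fit_gamma_regression(ds.design, ds.y,
                                   ModelSpec("shape_scale", COVS))
        fit.theta_scale[:] = 0.0
        t = wald_joint_test(fit, "scale")
        assert t.statistic == 0.0
        assert t.p_value == 1.0

    def test_requires_shape_scale_fit(self, dataset_n1000):
        ds = dataset_n1000
        fit = fit_gamma_regression(ds.design, ds.y, ModelSpec("shape", COVS))
        with pytest.raises(ValueError, match="shape_scale"):
            wald_joint_test(fit, "shape")

    def test_detects_which_parameter_carries_covariates(self):
        """On shape-DGP data the shape block rejects decisively while the
        scale block does not (covariates act only through the shape)."""
        rejections = {"shape": 0, "scale": 0}
        children = np.random.SeedSequence(424242).spawn(20)
        for ch in children:
            ds = simulate_shape_dgp(1000, seed=ch)
            fit = fit_gamma_regression(ds.design, ds.y,
                                       ModelSpec("shape_scale", COVS))
            for block in rejections:
                if wald_joint_test(fit, block).p_value < 0.05:
                    rejections[block] += 1
        assert rejections["shape"] == 20
        assert rejections["scale"] <= 5
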