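"""Gaussian Process machinery: kernels, likelihood, fitting, validation.

The exact-GP identities are checked against a naive dense-inverse oracle
(explicit matrix inverse and determinant), which is independent of the
Cholesky path used by the implementation.
"""

import math

import numpy as np
import pytest

from lakemwat.gp_surrogate import (
    KernelSpec,
    NormalizationConstants,
    _neg_lml_and_grad,
    aic,
    bootstrap_cv,
    default_kernel_candidates,
    fit,
    fit_statistics,
    gp_from_dict,
    gp_to_dict,
    kernel_eval,
    log_marginal_likelihood,
    pack_params,
    predict,
    rq_kernel,
    se_kernel,
    select_kernel,
    unpack_params,
)


def naive_lml(X, y, spec, noise):
    """Dense-inverse oracle for the exact-GP log marginal likelihood."""
    K = kernel_eval(spec, X, X) + noise * np.eye(len(y))
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    return float(-0.5 * y @ np.linalg.inv(K) @ y - 0.5 * logdet
                 - 0.5 * len(y) * math.log(2 * math.pi))


def naive_predict(X, y, spec, noise, Xq):
    Kinv = np.linalg.inv(kernel_eval(spec, X, X) + noise * np.eye(len(y)))
    Ks = kernel_eval(spec, Xq, X)
    mean = Ks @ Kinv @ y
    var = (np.diag(kernel_eval(spec, Xq, Xq)) - np.sum((Ks @ Kinv) * Ks, axis=1)
           + noise)
    return mean, var


class TestKernels:
    def test_total_variance_at_zero_distance(self):
        x = np.array([1.0, 2.0])
        assert kernel_eval(se_kernel(2, v=1.7), x, x) == pytest.approx(1.7)
        sum_spec = KernelSpec("sum", (se_kernel(2, 1.2), rq_kernel(2, 0.8)))
        assert kernel_eval(sum_spec, x, x) == pytest.approx(2.0)

    def test_squared_exponential_closed_form(self):
        spec = se_kernel(1)
        val = kernel_eval(spec, np.array([0.0]), np.array([1.0]))
        assert val == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_rq_converges_to_se(self, rng):
        se = se_kernel(3, v=1.3)
        rq = KernelSpec("rational_quadratic", signal_variance=1.3,
                        lengthscales=(1.0, 1.0, 1.0), rq_alpha=1e6)
        for _ in range(100):
            x1, x2 = rng.normal(size=3), rng.normal(size=3)
            assert kernel_eval(rq, x1, x2) == pytest.approx(
                kernel_eval(se, x1, x2), abs=1e-4)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval(se_kernel(2), np.array([1.0]), np.array([2.0]))

    @pytest.mark.parametrize("name", ["se", "rq", "matern32", "matern52",
                                      "linear", "se_plus_rq", "se_times_rq"])
    def test_gram_symmetric_psd(self, name, rng):
        spec = default_kernel_candidates(2)[name]
        X = rng.normal(size=(15, 2))
        K = kernel_eval(spec, X, X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert w.min() > -1e-8

    @pytest.mark.parametrize("name", ["se", "rq", "matern32", "matern52",
                                      "linear", "se_plus_rq", "se_times_rq"])
    def test_analytic_gradients_match_finite_differences(self, name, rng):
        spec = default_kernel_candidates(3)[name]
        # random log-parameters so derivatives are not probed at the template
        theta = rng.normal(0.0, 0.3, size=spec.n_params)
        spec = unpack_params(spec, theta)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        t_full = np.append(pack_params(spec), math.log(0.05))
        f0, g = _neg_lml_and_grad(t_full, spec, X, y)
        eps = 1e-6
        for i in range(len(t_full)):
            tp = t_full.copy()
            tp[i] += eps
            tm = t_full.copy()
            tm[i] -= eps
            fd = (_neg_lml_and_grad(tp, spec, X, y)[0]
                  - _neg_lml_and_grad(tm, spec, X, y)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-4, rel=1e-4)

    def test_random_hyperparameters_factorize(self, rng):
        """Gram matrices remain PSD (Cholesky-with-jitter) over random draws."""
        for _ in range(50):
            spec = unpack_params(se_kernel(2),
                                 rng.uniform(-2, 2, size=3))
            X = rng.normal(size=(10, 2))
            lml = log_marginal_likelihood(X, rng.normal(size=10), spec, 1e-6)
            assert np.isfinite(lml)


class TestMarginalLikelihood:
    def test_single_point_closed_form(self):
        # k(x,x) + noise = 1, y = 0 -> -0.5 log 2 pi
        spec = se_kernel(1, v=0.6)
        lml = log_marginal_likelihood(np.array([[0.0]]), np.array([0.0]),
                                      spec, 0.4)
        assert lml == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_oracle_n3(self, rng):
        X = rng.normal(size=(3, 2))
        y = rng.normal(size=3)
        spec = rq_kernel(2, v=1.4, alpha=0.7)
        assert log_marginal_likelihood(X, y, spec, 0.1) == pytest.approx(
            naive_lml(X, y, spec, 0.1), abs=1e-10)

    def test_zero_response_reduces_to_determinant_term(self, rng):
        X = rng.normal(size=(5, 2))
        spec = se_kernel(2)
        lml0 = log_marginal_likelihood(X, np.zeros(5), spec, 0.2)
        K = kernel_eval(spec, X, X) + 0.2 * np.eye(5)
        expected = -0.5 * np.linalg.slogdet(K)[1] - 2.5 * math.log(2 * math.pi)
        assert lml0 == pytest.approx(expected, abs=1e-10)


class TestExactOracleEquivalence:
    @pytest.mark.parametrize("n,name", [(5, "se"), (8, "se_plus_rq"),
                                        (10, "matern52")])
    def test_likelihood_mean_variance(self, n, name, rng):
        """Marginal likelihood and predictive moments match the naive
        dense-inverse implementation to 1e-8 on small fixtures."""
        spec = default_kernel_candidates(2)[name]
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        Xq = rng.normal(size=(4, 2))
        noise = 0.05
        assert log_marginal_likelihood(X, y, spec, noise) == pytest.approx(
            naive_lml(X, y, spec, noise), abs=1e-8)
        # exercise the TrainedGP path at fixed hyperparameters
        from lakemwat.gp_surrogate import TrainedGP, _factorize
        gp = _factorize(TrainedGP(
            features=X, responses=y, kernel=spec, noise_variance=noise,
            norm=NormalizationConstants(0.0, 1.0),
            feature_mean=np.zeros(2), feature_sd=np.ones(2),
            log_marginal_likelihood=0.0, n_hyperparameters=spec.n_params + 1))
        pred = predict(gp, Xq)
        mean, var = naive_predict(X, y, spec, noise, Xq)
        np.testing.assert_allclose(pred.mean, mean, atol=1e-8)
        np.testing.assert_allclose(pred.sd ** 2, var, atol=1e-8)


class TestFit:
    def test_parameter_recovery_from_known_gp(self):
        """Lengthscales of a known SE-kernel GP are recovered within x2."""
        rng = np.random.default_rng(1234)
        n, d = 100, 2
        X = rng.uniform(-3, 3, size=(n, d))
        true = se_kernel(d, v=1.0)
        K = kernel_eval(true, X, X) + 0.01 * np.eye(n)
        y = np.linalg.cholesky(K) @ rng.normal(size=n)
        y = 5.0 + 2.0 * y  # arbitrary scale, removed by normalization
        gp = fit(X, y, se_kernel(d), restarts=5, seed=0)
        x_sd = X.std(axis=0)
        for j, ell in enumerate(gp.kernel.lengthscales):
            recovered = ell * x_sd[j]  # back to raw feature scale
            assert 0.5 <= recovered <= 2.0

    def test_constant_responses_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="constant"):
            fit(X, np.full(10, 3.0), se_kernel(2))

    def test_refit_same_seed_identical(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, size=20)
        a = fit(X, y, se_kernel(2), restarts=3, seed=7)
        b = fit(X, y, se_kernel(2), restarts=3, seed=7)
        assert a.kernel == b.kernel
        assert a.noise_variance == b.noise_variance

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit(rng.normal(size=(3, 2)), rng.normal(size=3), se_kernel(2))


class TestPredict:
    @pytest.fixture()
    def toy_gp(self, rng):
        X = rng.uniform(-2, 2, size=(12, 2))
        y = 20.0 + 3.0 * np.sin(X[:, 0]) + rng.normal(0, 0.05, size=12)
        return fit(X, y, se_kernel(2), restarts=3, seed=1), X, y

    def test_prior_reversion_far_from_data(self, toy_gp):
        gp, X, y = toy_gp
        far = np.array([500.0, -500.0])
        pred = predict(gp, far)
        assert pred.mean == pytest.approx(gp.norm.mean, rel=0.01)
        v_total = kernel_eval(gp.kernel, np.zeros(2), np.zeros(2))
        expected_sd = math.sqrt(v_total + gp.noise_variance) * gp.norm.sd
        assert pred.sd == pytest.approx(expected_sd, rel=0.01)

    def test_interpolation_at_training_point(self, rng):
        X = rng.uniform(-2, 2, size=(10, 2))
        y = 15.0 + np.cos(X[:, 1])
        gp = fit(X, y, se_kernel(2), restarts=2, seed=3)
        gp.noise_variance = 1e-9
        from lakemwat.gp_surrogate import _factorize
        _factorize(gp)
        pred = predict(gp, X[4])
        assert pred.mean == pytest.approx(y[4], abs=1e-3)

    def test_interval_ordering_and_variance_bounds(self, toy_gp, rng):
        gp, X, y = toy_gp
        Xq = rng.uniform(-3, 3, size=(50, 2))
        pred = predict(gp, Xq)
        assert np.all(pred.lower95 <= pred.mean)
        assert np.all(pred.mean <= pred.upper95)
        v_total = kernel_eval(gp.kernel, np.zeros(2), np.zeros(2))
        var_norm = (pred.sd / gp.norm.sd) ** 2
        assert np.all(var_norm >= gp.noise_variance * (1 - 1e-6))
        assert np.all(var_norm <= v_total + gp.noise_variance + 1e-8)

    def test_dimension_mismatch_rejected(self, toy_gp):
        gp, _, _ = toy_gp
        with pytest.raises(ValueError):
            predict(gp, np.array([1.0, 2.0, 3.0]))

    def test_persistence_round_trip(self, toy_gp, rng):
        gp, _, _ = toy_gp
        back = gp_from_dict(gp_to_dict(gp))
        Xq = rng.normal(size=(5, 2))
        np.testing.assert_array_equal(predict(back, Xq).mean,
                                      predict(gp, Xq).mean)


class TestAIC:
    def test_arithmetic(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, size=15)
        gp = fit(X, y, se_kernel(2), restarts=2, seed=0)
        assert aic(gp) == pytest.approx(
            2 * gp.n_hyperparameters - 2 * gp.log_marginal_likelihood)
        gp.n_hyperparameters += 1
        assert aic(gp) == pytest.approx(
            2 * (gp.n_hyperparameters - 1) - 2 * gp.log_marginal_likelihood + 2)

    def test_sum_kernel_likelihood_contains_children(self, rng):
        """The sum kernel's optimum is at least as good as its best child's
        (containment of hypothesis spaces), up to optimizer slack."""
        X = rng.uniform(-2, 2, size=(30, 2))
        y = np.sin(1.5 * X[:, 0]) + 0.3 * X[:, 1] + rng.normal(0, 0.1, size=30)
        child = fit(X, y, se_kernel(2), restarts=4, seed=2)
        parent = fit(X, y, KernelSpec("sum", (se_kernel(2), rq_kernel(2))),
                     restarts=4, seed=2)
        assert parent.log_marginal_likelihood >= child.log_marginal_likelihood - 0.3


class TestSelectKernel:
    def test_single_candidate_trivial_ranking(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, size=15)
        ranking, fits = select_kernel(X, y, {"se": se_kernel(2)}, restarts=2,
                                      seed=0)
        assert list(ranking["kernel"]) == ["se"] and "se" in fits

    def test_ranking_sorted_by_aic(self, rng):
        X = rng.uniform(-2, 2, size=(25, 2))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, size=25)
        cands = {k: v for k, v in default_kernel_candidates(2).items()
                 if k in ("se", "matern32", "linear")}
        ranking, _ = select_kernel(X, y, cands, restarts=2, seed=0)
        assert ranking["aic"].is_monotonic_increasing

    def test_pure_noise_close_to_iid_gaussian(self, rng):
        """On pure-noise responses every kernel's likelihood approaches the
        closed-form i.i.d. Gaussian explanation (within the 2k AIC spread)."""
        n = 40
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        sigma2 = y.var()
        iid_ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
        cands = {k: v for k, v in default_kernel_candidates(2).items()
                 if k in ("se", "rq", "linear")}
        ranking, fits = select_kernel(X, y, cands, restarts=3, seed=1)
        for name, gp in fits.items():
            assert gp.log_marginal_likelihood >= iid_ll - 1.0
            assert aic(gp) <= 2 * gp.n_hyperparameters - 2 * iid_ll + 2.0


class TestBootstrapCV:
    def test_noise_free_linear_recovered(self, rng):
        X = rng.uniform(-1, 1, size=(40, 2))
        y = 20.0 + 2.0 * X[:, 0] - 1.0 * X[:, 1]
        res = bootstrap_cv(X, y, KernelSpec("linear"), B=10, seed=0, restarts=2)
        assert res.mean_absolute_error < 0.05

    def test_determinism(self, rng):
        X = rng.uniform(-1, 1, size=(25, 2))
        y = np.sin(2 * X[:, 0]) + rng.normal(0, 0.1, size=25)
        a = bootstrap_cv(X, y, se_kernel(2), B=10, seed=5, restarts=1)
        b = bootstrap_cv(X, y, se_kernel(2), B=10, seed=5, restarts=1)
        assert a.replicates.equals(b.replicates)
        np.testing.assert_array_equal(a.errors, b.errors)

    def test_minimum_replicates_enforced(self, rng):
        with pytest.raises(ValueError):
            bootstrap_cv(rng.normal(size=(10, 1)), rng.normal(size=10),
                         se_kernel(1), B=5)


class TestFitStatistics:
    def test_near_perfect_fit(self, rng):
        X = rng.uniform(-2, 2, size=(15, 1))
        y = 10.0 + np.sin(X[:, 0])
        gp = fit(X, y, se_kernel(1), restarts=3, seed=0)
        stats = fit_statistics(gp, X, y)
        assert stats.r_squared > 0.99
        assert stats.rmse < 0.1

    def test_matches_manual_computation(self, rng):
        X = rng.uniform(-2, 2, size=(15, 2))
        y = 10.0 + np.sin(X[:, 0]) + rng.normal(0, 0.3, size=15)
        gp = fit(X, y, se_kernel(2), restarts=2, seed=0)
        pred = predict(gp, X).mean
        stats = fit_statistics(gp, X, y)
        resid = y - pred
        assert stats.rmse == pytest.approx(np.sqrt(np.mean(resid ** 2)))
        assert stats.mae == pytest.approx(np.mean(np.abs(resid)))
        assert stats.r_squared == pytest.approx(
            1 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))


class TestNormalization:
    def test_round_trip_exact(self):
        norm = NormalizationConstants(25.65, 3.265)
        assert norm.normalize(25.65) == 0.0
        x = np.array([18.2, 25.65, 31.9])
        np.testing.assert_array_equal(norm.denormalize(norm.normalize(x)), x)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            NormalizationConstants(0.0, 0.0)
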