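"""Exponential-kernel GPR: closed forms, dense oracles, fitting behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgbp import gpr
from ppgbp.errors import InvalidConfigError


def _identity_model(X, y, params) -> gpr.GPRModel:
    """Model in raw units (identity standardizer), fixed hyperparameters."""
    std = gpr.Standardizer(
        x_mean=np.zeros(X.shape[1]), x_scale=np.ones(X.shape[1]), y_mean=0.0, y_scale=1.0
    )
    return gpr.GPRModel(training=gpr.TrainingSet(X, y), params=params, standardizer=std)


def _dense_predict(X, y, params, xq):
    """Naive-inverse oracle for the predictive mean and variance."""
    K = gpr.kernel_matrix(X, X, params) + params.sigma_n2 * np.eye(len(y))
    Kinv = np.linalg.inv(K)
    kq = gpr.kernel_matrix(X, xq[None, :], params).ravel()
    mean = kq @ Kinv @ y
    var = params.sigma_f**2 - kq @ Kinv @ kq
    return mean, var


class TestKernel:
    def test_self_covariance_is_signal_variance(self):
        params = gpr.KernelParams(sigma_f=2.0, sigma_l=1.0, sigma_n2=0.0)
        x = np.array([0.3, -1.2, 4.0])
        assert gpr.kernel_eval(x, x, params) == pytest.approx(4.0, abs=1e-12)

    def test_unit_distance_closed_form(self):
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=1.0, sigma_n2=0.0)
        assert gpr.kernel_eval([0.0], [1.0], params) == pytest.approx(
            np.exp(-1.0), abs=1e-9
        )

    def test_euclidean_variant(self):
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=2.0, sigma_n2=0.0, distance="euclidean")
        assert gpr.kernel_eval([0.0], [3.0], params) == pytest.approx(np.exp(-1.5), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_bound(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=5)
        params = gpr.KernelParams(sigma_f=1.7, sigma_l=0.9, sigma_n2=0.0)
        kab = gpr.kernel_eval(a, b, params)
        assert kab == pytest.approx(gpr.kernel_eval(b, a, params), abs=1e-12)
        assert kab <= params.sigma_f**2 + 1e-12

    def test_dimension_mismatch_rejected(self):
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=1.0, sigma_n2=0.0)
        with pytest.raises(InvalidConfigError):
            gpr.kernel_eval([0.0, 1.0], [0.0], params)


class TestLogMarginalLikelihood:
    def test_diagonal_case_is_sum_of_scalar_gaussians(self):
        """Far-apart points: the LML separates into independent scalars."""
        params = gpr.KernelParams(sigma_f=1.3, sigma_l=1e-4, sigma_n2=0.5)
        X = np.array([[0.0], [100.0]])
        y = np.array([0.7, -1.1])
        v = params.sigma_f**2 + params.sigma_n2
        expected = sum(
            -0.5 * yi**2 / v - 0.5 * np.log(v) - 0.5 * np.log(2 * np.pi) for yi in y
        )
        got = gpr.log_marginal_likelihood(gpr.TrainingSet(X, y), params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 21))
            X = rng.normal(size=(n, 4))
            y = rng.normal(size=n)
            params = gpr.KernelParams(
                sigma_f=float(rng.uniform(0.5, 2)),
                sigma_l=float(rng.uniform(0.5, 3)),
                sigma_n2=float(rng.uniform(0.05, 0.5)),
            )
            K = gpr.kernel_matrix(X, X, params) + params.sigma_n2 * np.eye(n)
            expected = (
                -0.5 * y @ np.linalg.inv(K) @ y
                - 0.5 * np.log(np.linalg.det(K))
                - 0.5 * n * np.log(2 * np.pi)
            )
            got = gpr.log_marginal_likelihood(gpr.TrainingSet(X, y), params)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=1.0, sigma_n2=0.1)
        perm = rng.permutation(12)
        a = gpr.log_marginal_likelihood(gpr.TrainingSet(X, y), params)
        b = gpr.log_marginal_likelihood(gpr.TrainingSet(X[perm], y[perm]), params)
        assert a == pytest.approx(b, abs=1e-9)


class TestPredict:
    def test_noise_free_interpolation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=2.0, sigma_n2=1e-12)
        model = _identity_model(X, y, params)
        for i in range(15):
            mean, _ = gpr.predict(model, X[i])
            assert mean == pytest.approx(y[i], abs=1e-6)

    def test_far_query_reverts_to_prior(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10) + 120.0
        std = gpr.Standardizer(
            x_mean=X.mean(0), x_scale=X.std(0), y_mean=float(y.mean()), y_scale=float(y.std())
        )
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=1.0, sigma_n2=0.1)
        Xs = std.transform_x(X)
        model = gpr.GPRModel(
            training=gpr.TrainingSet(Xs, std.transform_y(y)), params=params, standardizer=std
        )
        far = X.mean(0) + 100.0 * X.std(0)
        mean, var = gpr.predict(model, far)
        assert mean == pytest.approx(y.mean(), abs=1e-6)
        assert var == pytest.approx(params.sigma_f**2 * std.y_scale**2, rel=1e-6)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(3, 21))
            X = rng.normal(size=(n, 5))
            y = rng.normal(size=n)
            params = gpr.KernelParams(
                sigma_f=float(rng.uniform(0.5, 2)),
                sigma_l=float(rng.uniform(0.5, 3)),
                sigma_n2=float(rng.uniform(0.01, 0.3)),
            )
            model = _identity_model(X, y, params)
            xq = rng.normal(size=5)
            mean, var = gpr.predict(model, xq)
            mean_o, var_o = _dense_predict(X, y, params, xq)
            assert mean == pytest.approx(mean_o, abs=1e-8)
            assert var == pytest.approx(var_o, abs=1e-8)

    def test_variance_bounds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        params = gpr.KernelParams(sigma_f=1.4, sigma_l=1.0, sigma_n2=0.05)
        model = _identity_model(X, y, params)
        for _ in range(20):
            _, var = gpr.predict(model, rng.normal(size=4))
            assert 0.0 <= var <= params.sigma_f**2 + 1e-12

    def test_extra_point_never_raises_variance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        params = gpr.KernelParams(sigma_f=1.0, sigma_l=1.5, sigma_n2=0.1)
        model = _identity_model(X, y, params)
        grown = gpr.augment(model, rng.normal(size=(1, 3)), np.array([0.3]))
        for _ in range(15):
            xq = rng.normal(size=3)
            assert gpr.predict(grown, xq)[1] <= gpr.predict(model, xq)[1] + 1e-10

    def test_dimension_mismatch_rejected(self):
        model = _identity_model(
            np.zeros((3, 2)),
            np.zeros(3),
            gpr.KernelParams(sigma_f=1.0, sigma_l=1.0, sigma_n2=0.1),
        )
        with pytest.raises(InvalidConfigError):
            gpr.predict(model, [1.0, 2.0, 3.0])

    def test_matches_sklearn_reference(self):
        """Cross-check against scikit-learn's GP with the equivalent RBF kernel."""
        sklearn = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        params = gpr.KernelParams(sigma_f=1.2, sigma_l=2.0, sigma_n2=0.09)
        # exp(-d^2 / sigma_l) == RBF with length_scale = sqrt(sigma_l / 2)
        ref = GaussianProcessRegressor(
            kernel=ConstantKernel(params.sigma_f**2, "fixed")
            * RBF(np.sqrt(params.sigma_l / 2.0), "fixed"),
            alpha=params.sigma_n2,
            optimizer=None,
        ).fit(X, y)
        model = _identity_model(X, y, params)
        Xq = rng.normal(size=(8, 3))
        mu_ref, sd_ref = ref.predict(Xq, return_std=True)
        for i, xq in enumerate(Xq):
            mean, var = gpr.predict(model, xq)
            assert mean == pytest.approx(mu_ref[i], abs=1e-8)
            assert var == pytest.approx(sd_ref[i] ** 2, abs=1e-8)


class TestFit:
    def test_zero_targets_predict_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        model = gpr.fit_gpr(gpr.TrainingSet(X, np.zeros(20)), gpr.FitOptions(seed=0))
        mean, _ = gpr.predict(model, rng.normal(size=3))
        assert mean == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, 30)
        a = gpr.fit_gpr(gpr.TrainingSet(X, y), gpr.FitOptions(seed=5))
        b = gpr.fit_gpr(gpr.TrainingSet(X, y), gpr.FitOptions(seed=5))
        assert a.params == b.params
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_hyperparameter_recovery(self):
        """Simulated-GP hyperparameters recovered within a factor of two."""
        true = gpr.KernelParams(sigma_f=1.5, sigma_l=2.0, sigma_n2=0.09)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-2, 2, size=(100, 2))
            K = gpr.kernel_matrix(X, X, true) + true.sigma_n2 * np.eye(100)
            y = rng.multivariate_normal(np.zeros(100), K)
            model = gpr.fit_gpr(gpr.TrainingSet(X, y), gpr.FitOptions(seed=seed))
            st_ = model.standardizer
            est = {
                "sigma_f": model.params.sigma_f * st_.y_scale,
                "sigma_l": model.params.sigma_l * float(np.mean(st_.x_scale**2)),
                "sigma_n": np.sqrt(model.params.sigma_n2) * st_.y_scale,
            }
            ref = {"sigma_f": 1.5, "sigma_l": 2.0, "sigma_n": 0.3}
            if all(0.5 <= est[k] / ref[k] <= 2.0 for k in ref):
                ok += 1
        assert ok >= 16  # >= 80% of 20 seeded runs

    def test_heldout_beats_noise_floor(self):
        """On a smooth 1-D function the GP mean denoises the observations."""
        rng = np.random.default_rng(11)
        x = rng.uniform(-3, 3, 150)
        noise_sd = 0.3
        y = np.sin(x) + rng.normal(0, noise_sd, 150)
        model = gpr.fit_gpr(
            gpr.TrainingSet(x[:100, None], y[:100]), gpr.FitOptions(seed=0)
        )
        preds = np.array([gpr.predict(model, [xi])[0] for xi in x[100:]])
        rmse = np.sqrt(np.mean((preds - np.sin(x[100:])) ** 2))
        assert rmse < noise_sd

    def test_augment_with_nothing_is_identity(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(10, 2))
        model = _identity_model(
            X, rng.normal(size=10), gpr.KernelParams(sigma_f=1.0, sigma_l=1.0, sigma_n2=0.1)
        )
        assert gpr.augment(model, np.empty((0, 2)), np.empty(0)) is model

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = gpr.fit_gpr(gpr.TrainingSet(X, y), gpr.FitOptions(seed=1))
        clone = gpr.model_from_dict(gpr.model_to_dict(model))
        xq = rng.normal(size=3)
        assert gpr.predict(clone, xq) == pytest.approx(gpr.predict(model, xq), abs=1e-12)
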