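"""LS-SVM core: kernel values, dual-solve correctness against a dense oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecohealth.lssvm import (
    KernelParams,
    LSSVMModel,
    LSSVMValidationError,
    fit,
    loo_residuals,
    predict,
    rbf_kernel,
)


def dense_kkt_oracle(X, y, params):
    """Independent solve of the full bordered KKT system (the written equations)."""
    n = len(y)
    K = np.exp(
        -np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2) / (2 * params.sigma**2)
    )
    M = np.zeros((n + 1, n + 1))
    M[0, 1:] = 1.0
    M[1:, 0] = 1.0
    M[1:, 1:] = K + np.eye(n) / params.gamma
    sol = np.linalg.solve(M, np.concatenate(([0.0], y)))
    return sol[0], sol[1:]


class TestKernel:
    def test_closed_form_values(self):
        x = np.array([1.0, 2.0])
        assert rbf_kernel(x, x, sigma=0.7) == pytest.approx(1.0)
        # squared distance 2*sigma^2 gives exactly exp(-1)
        sigma = 1.5
        x2 = x + np.array([np.sqrt(2.0) * sigma, 0.0])
        assert rbf_kernel(x, x2, sigma) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_wide_kernel_limit(self):
        x, x2 = np.array([0.0, 0.0]), np.array([3.0, -4.0])
        assert rbf_kernel(x, x2, sigma=1e6) == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(LSSVMValidationError):
            rbf_kernel(np.array([1.0]), np.array([1.0, 2.0]), sigma=1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=2, max_size=4
        ),
        st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=2, max_size=4
        ),
        st.floats(0.1, 10.0),
    )
    def test_symmetry_and_bounds(self, a, b, sigma):
        d = min(len(a), len(b))
        x, x2 = np.array(a[:d]), np.array(b[:d])
        k = rbf_kernel(x, x2, sigma)
        # mathematically in (0, 1]; tiny values may underflow to exactly 0
        assert 0.0 <= k <= 1.0
        if np.sum((x - x2) ** 2) < 500 * sigma**2:
            assert k > 0.0
        assert k == pytest.approx(rbf_kernel(x2, x, sigma))


class TestFit:
    def test_constant_targets_give_zero_alphas_and_bias_c(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        model = fit(X, np.full(6, 3.25), KernelParams(1.0, 5.0))
        np.testing.assert_allclose(model.alphas, 0.0, atol=1e-10)
        assert model.bias == pytest.approx(3.25, abs=1e-10)
        np.testing.assert_allclose(predict(model, X), 3.25, atol=1e-9)

    def test_interpolation_limit_of_vanishing_regularization(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit(X, y, KernelParams(1.0, 1e8))
        resid = np.abs(predict(model, X) - y)
        assert resid.max() <= 1e-4 * np.ptp(y)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_dense_kkt_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        d = int(rng.integers(1, 8))
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        params = KernelParams(
            float(np.exp(rng.uniform(np.log(0.5), np.log(5)))),
            float(np.exp(rng.uniform(np.log(0.1), np.log(100)))),
        )
        model = fit(X, y, params)
        b_ref, alpha_ref = dense_kkt_oracle(X, y, params)
        assert abs(model.bias - b_ref) <= 1e-10
        assert np.abs(model.alphas - alpha_ref).max() <= 1e-10
        assert abs(model.alphas.sum()) <= 1e-8 * max(1.0, np.abs(y).sum())
        assert model.kkt_residual <= 1e-8

    def test_training_mse_nonincreasing_in_gamma(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=12)
        prev = np.inf
        for gamma in [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]:
            model = fit(X, y, KernelParams(1.0, gamma))
            mse = float(np.mean((predict(model, X) - y) ** 2))
            assert mse <= prev + 1e-12
            prev = mse

    def test_prediction_invariant_to_sample_order(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 2))
        y = rng.normal(size=9)
        grid = rng.normal(size=(5, 2))
        params = KernelParams(1.2, 8.0)
        perm = rng.permutation(9)
        a = predict(fit(X, y, params), grid)
        b = predict(fit(X[perm], y[perm], params), grid)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_validation_errors(self):
        with pytest.raises(LSSVMValidationError):
            fit(np.ones((1, 2)), np.ones(1), KernelParams(1.0, 1.0))
        with pytest.raises(LSSVMValidationError):
            KernelParams(-1.0, 1.0)
        model = fit(np.ones((3, 2)) + np.arange(3)[:, None], np.arange(3.0), KernelParams(1.0, 1.0))
        with pytest.raises(LSSVMValidationError):
            predict(model, np.ones((2, 5)))


class TestPredict:
    def test_bias_only_model(self):
        model = LSSVMModel(
            alphas=np.zeros(3),
            bias=3.5,
            train_inputs=np.eye(3),
            params=KernelParams(1.0, 1.0),
        )
        np.testing.assert_allclose(predict(model, np.random.default_rng(1).normal(size=(4, 3))), 3.5)

    def test_two_point_fit_evaluated_off_sample_matches_oracle_arithmetic(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 2.0])
        params = KernelParams(0.8, 50.0)
        b_ref, alpha_ref = dense_kkt_oracle(X, y, params)
        x_new = np.array([[0.4]])
        expected = (
            alpha_ref[0] * np.exp(-0.4**2 / (2 * 0.8**2))
            + alpha_ref[1] * np.exp(-0.6**2 / (2 * 0.8**2))
            + b_ref
        )
        model = fit(X, y, params)
        assert predict(model, x_new)[0] == pytest.approx(expected, abs=1e-10)


def test_loo_shortcut_matches_explicit_refits():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(8, 3))
    y = rng.normal(size=8)
    params = KernelParams(1.1, 15.0)
    closed = loo_residuals(X, y, params)
    explicit = np.empty(8)
    for i in range(8):
        mask = np.arange(8) != i
        model = fit(X[mask], y[mask], params)
        explicit[i] = y[i] - predict(model, X[i][None, :])[0]
    np.testing.assert_allclose(closed, explicit, atol=1e-10)


def test_text_serialization_round_trip():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(5, 2))
    y = rng.normal(size=5)
    model = fit(X, y, KernelParams(1.4, 12.0))
    back = LSSVMModel.from_text(model.to_text())
    grid = rng.normal(size=(4, 2))
    np.testing.assert_allclose(predict(back, grid), predict(model, grid), rtol=0, atol=0)
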