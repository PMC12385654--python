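"""RBF network, Elman network and quadratic response surface."""

import numpy as np
import pytest

import wolfberry as wb
from wolfberry.surrogates import (
    ElmanSurrogate,
    TrainProtocol,
    elman_forward,
    elman_predict,
    elman_train,
    evaluate_model,
    fit_quadratic_rsm,
    gaussian_basis,
    quadratic_basis,
    rbf_predict,
    rbf_train,
    rsm_evaluate,
    rsm_evaluate_batch,
    train_test_split,
)

INTERP_PROTOCOL = TrainProtocol(rbf_width_grid=(0.3,))


class TestGaussianBasis:
    def test_at_center(self):
        assert gaussian_basis([0.2, 0.3], [0.2, 0.3], 1.0) == 1.0

    def test_unit_exponent(self):
        # squared distance equal to 2 width^2 gives exactly exp(-1)
        width = 0.5
        x = np.array([0.0, 0.0])
        c = np.array([np.sqrt(2.0) * width, 0.0])
        assert gaussian_basis(x, c, width) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_monotone_decreasing_and_bounded(self):
        values = [gaussian_basis([r, 0.0], [0.0, 0.0], 0.7) for r in np.linspace(0, 3, 40)]
        assert all(0 < v <= 1 for v in values)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            gaussian_basis([0.0], [0.0], 0.0)


class TestRBFPredict:
    def _model(self, centers, weights, width=1.0):
        return wb.RBFSurrogate(
            centers=np.asarray(centers, float),
            width=width,
            weights=np.asarray(weights, float),
            response_names=tuple(f"y{i}" for i in range(np.asarray(weights).shape[1])),
        )

    def test_zero_weights(self):
        m = self._model([[0.0, 0.0]], [[0.0, 0.0]])
        np.testing.assert_array_equal(rbf_predict(m, [0.3, 0.4]), [0.0, 0.0])

    def test_single_center_at_point(self):
        m = self._model([[0.2, 0.8]], [[1.5, -2.0]])
        np.testing.assert_allclose(rbf_predict(m, [0.2, 0.8]), [1.5, -2.0], atol=1e-12)

    def test_two_center_arithmetic(self):
        m = self._model([[1.0, 0.0], [2.0, 0.0]], [[1.0], [1.0]])
        out = rbf_predict(m, [0.0, 0.0])
        assert out[0] == pytest.approx(np.exp(-0.5) + np.exp(-2.0), abs=1e-4)

    def test_shape_error(self):
        m = self._model([[0.0, 0.0]], [[1.0]])
        with pytest.raises(ValueError):
            rbf_predict(m, [0.0, 0.0, 0.0])


class TestRBFTrain:
    def test_constant_targets(self, rng):
        X = rng.random((12, 3))
        Y = np.full((12, 2), 7.5)
        m = rbf_train(X, Y, INTERP_PROTOCOL)
        np.testing.assert_allclose(m.predict(X), Y, atol=1e-6)

    def test_interpolation_at_training_points(self, table2):
        m = rbf_train(table2.X, table2.Y, INTERP_PROTOCOL, table2.response_names)
        assert np.abs(m.predict(table2.X) - table2.Y).max() < 1e-6

    def test_recovers_quadratic_surface(self, ref_rsm):
        grid = np.stack(
            np.meshgrid(*[np.linspace(0, 1, 5)] * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        Y = rsm_evaluate_batch(ref_rsm, grid)
        tr, te = train_test_split(len(grid), 0.8, seed=0)
        m = rbf_train(grid[tr], Y[tr], TrainProtocol(), ref_rsm.response_names)
        mets = evaluate_model(m.predict, grid[te], Y[te], ref_rsm.response_names)
        assert all(v.r2 > 0.999 for v in mets.values())

    def test_duplicate_inputs_warn(self):
        X = np.array([[0.5, 0.5], [0.5, 0.5], [0.1, 0.9]])
        Y = np.array([[1.0], [1.0], [2.0]])
        with pytest.warns(RuntimeWarning, match="duplicate"):
            rbf_train(X, Y, TrainProtocol(rbf_width_grid=(0.5,)))

    def test_width_grid_includes_cv_choice(self, table2):
        m = rbf_train(table2.X, table2.Y, TrainProtocol(), table2.response_names)
        assert m.width in TrainProtocol().rbf_width_grid
        assert set(m.cv_scores) == set(TrainProtocol().rbf_width_grid)

    def test_matches_scipy_rbf_interpolator(self, table2):
        """Independent oracle: same kernel, same data, same predictions."""
        from scipy.interpolate import RBFInterpolator

        width = 0.3
        m = rbf_train(table2.X, table2.Y, TrainProtocol(rbf_width_grid=(width,)))
        # scipy's gaussian kernel is exp(-(eps r)^2); ours exp(-r^2 / 2 sigma^2)
        oracle = RBFInterpolator(
            table2.X, table2.Y, kernel="gaussian", epsilon=1.0 / (width * np.sqrt(2.0)),
            smoothing=0.0, degree=-1,
        )
        pts = np.random.default_rng(0).random((25, 3))
        np.testing.assert_allclose(m.predict(pts), oracle(pts), rtol=1e-4, atol=1e-4)


class TestElmanForward:
    def test_zero_weights_zero_outputs(self):
        m = ElmanSurrogate(
            w_context_to_hidden=np.zeros((3, 3)),
            w_input_to_hidden=np.zeros((3, 2)),
            w_hidden_to_output=np.zeros((1, 3)),
            context_state=np.zeros(3),
        )
        outs = elman_forward(m, np.random.default_rng(0).random((5, 2)))
        assert all(np.all(o == 0.0) for o in outs)

    def test_hand_recursion_1_1_1(self):
        m = ElmanSurrogate(
            w_context_to_hidden=np.array([[0.5]]),
            w_input_to_hidden=np.array([[1.0]]),
            w_hidden_to_output=np.array([[2.0]]),
            context_state=np.zeros(1),
        )
        outs = elman_forward(m, [[1.0], [0.0]])
        # step 1: hidden = tanh(1) = 0.7616, output 1.5232
        # step 2: hidden = tanh(0.5 * 0.7616) = 0.3633, output 0.7266
        assert outs[0][0] == pytest.approx(1.5232, abs=1e-3)
        assert outs[1][0] == pytest.approx(0.7266, abs=1e-3)

    def test_context_stores_penultimate_hidden(self, rng):
        h, d = 4, 2
        m = ElmanSurrogate(
            w_context_to_hidden=rng.uniform(-0.5, 0.5, (h, h)),
            w_input_to_hidden=rng.uniform(-0.5, 0.5, (h, d)),
            w_hidden_to_output=rng.uniform(-0.5, 0.5, (1, h)),
            context_state=np.zeros(h),
        )
        seq = rng.random((6, d))
        elman_forward(m, seq)
        # replay the recursion to the penultimate hidden state
        xc = np.zeros(h)
        hidden = None
        for u in seq[:-1]:
            if hidden is not None:
                xc = hidden
            hidden = np.tanh(m.w_context_to_hidden @ xc + m.w_input_to_hidden @ u)
        np.testing.assert_allclose(m.context_state, hidden, atol=1e-12)

    def test_empty_sequence(self):
        m = ElmanSurrogate(
            w_context_to_hidden=np.zeros((2, 2)),
            w_input_to_hidden=np.zeros((2, 1)),
            w_hidden_to_output=np.zeros((1, 2)),
            context_state=np.zeros(2),
        )
        assert elman_forward(m, []) == []


class TestElmanTrain:
    def test_error_tolerance_stops_immediately(self, table2):
        proto = TrainProtocol(elman_error_tol=1e3)
        m = elman_train(table2.X, table2.Y, proto, table2.response_names)
        assert m.history["epochs"] == 1
        assert m.history["stop_reason"] == "error_tol"

    def test_training_reduces_mse_on_table2(self, table2):
        proto = TrainProtocol(init_seed=0, elman_max_epochs=200)
        m = elman_train(table2.X, table2.Y, proto, table2.response_names)
        assert m.history["final_mse"] <= m.history["initial_mse"]

    def test_learns_linear_function(self):
        gen = np.random.default_rng(0)
        X = gen.random((50, 3))
        Y = X[:, :1].copy()
        m = elman_train(X, Y, TrainProtocol(init_seed=1))
        mse = float(np.mean((elman_predict(m, X) - Y) ** 2))
        assert mse < 1e-3


class TestQuadraticRSM:
    def test_parameter_recovery(self, rng):
        true = rng.normal(size=(2, 10))
        X = rng.random((20, 3))
        Y = quadratic_basis(X) @ true.T
        fitted = fit_quadratic_rsm(X, Y)
        np.testing.assert_allclose(fitted.coefficients, true, atol=1e-8)

    def test_constant_response(self, rng):
        X = rng.random((15, 3))
        Y = np.full((15, 1), 4.2)
        fitted = fit_quadratic_rsm(X, Y)
        assert fitted.coefficients[0, 0] == pytest.approx(4.2, abs=1e-10)
        np.testing.assert_allclose(fitted.coefficients[0, 1:], 0.0, atol=1e-10)

    def test_rank_deficient_design(self):
        X = np.tile([[0.5, 0.5, 0.5]], (12, 1))
        with pytest.raises(np.linalg.LinAlgError):
            fit_quadratic_rsm(X, np.ones((12, 1)))

    def test_table2_fit_is_finite(self, table2):
        fitted = fit_quadratic_rsm(table2.X, table2.Y, table2.response_names)
        assert np.all(np.isfinite(fitted.coefficients))
        assert all(np.isfinite(r) for r in fitted.r2)

    def test_reference_ta_intercept(self, ref_rsm):
        assert rsm_evaluate(ref_rsm, np.zeros(3))[2] == 1.8548

    def test_reference_hardness_coefficient_sum(self, ref_rsm):
        assert rsm_evaluate(ref_rsm, np.ones(3))[0] == pytest.approx(1202.81, abs=0.01)

    def test_evaluation_linear_in_coefficients(self, ref_rsm, rng):
        doubled = wb.QuadraticRSM(2.0 * ref_rsm.coefficients, ref_rsm.response_names)
        x = rng.random(3)
        np.testing.assert_allclose(
            rsm_evaluate(doubled, x), 2.0 * rsm_evaluate(ref_rsm, x), rtol=1e-12
        )

    def test_warns_outside_cube(self, ref_rsm):
        with pytest.warns(RuntimeWarning):
            rsm_evaluate(ref_rsm, np.array([1.1, 0.5, 0.5]))

    def test_matches_sklearn_ols(self, table2):
        """Independent oracle: scikit-learn OLS over the same basis."""
        from sklearn.linear_model import LinearRegression

        B = quadratic_basis(table2.X)[:, 1:]
        ours = fit_quadratic_rsm(table2.X, table2.Y, table2.response_names)
        oracle = LinearRegression().fit(B, table2.Y)
        np.testing.assert_allclose(ours.coefficients[:, 1:], oracle.coef_, atol=1e-8)
        np.testing.assert_allclose(ours.coefficients[:, 0], oracle.intercept_, atol=1e-8)


class TestEvaluateModel:
    def test_perfect_predictor(self, table2):
        mets = evaluate_model(lambda X: table2.Y, table2.X, table2.Y, table2.response_names)
        for fm in mets.values():
            assert fm.r2 == pytest.approx(1.0)
            assert fm.rmse == 0.0

    def test_empty_test_set(self, table2):
        with pytest.raises(ValueError):
            evaluate_model(lambda X: X, np.empty((0, 3)), np.empty((0, 4)), table2.response_names)
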