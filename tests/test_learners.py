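import numpy as np
import pytest

from yieldforge.learners import (
    ACTIVATIONS,
    HiddenLayer,
    LearnerError,
    fit_elm,
    fit_oselm,
    fit_oselm_init,
    fit_rf_baseline,
    hidden_map,
    oselm_update,
    predict,
)


def regression_problem(seed=0, n=500, d=3, noise=0.2):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-3, 3, size=(n, d))
    y = np.sin(X).sum(axis=1) + noise * rng.standard_normal(n)
    return X, y


class TestHiddenMap:
    def test_logistic_at_zero_argument(self):
        layer = HiddenLayer(
            weights=np.zeros((3, 2)), biases=np.zeros(3), activation="sig", seed=0
        )
        H = hidden_map(layer, np.array([[5.0, -7.0]]))
        np.testing.assert_allclose(H, 0.5)

    def test_rbf_kernel_is_one_at_centre(self):
        centre = np.array([[0.3, -0.6]])
        layer = HiddenLayer(
            weights=centre, biases=np.array([0.8]), activation="rbf", seed=0
        )
        H = hidden_map(layer, centre)
        assert H[0, 0] == pytest.approx(1.0)

    def test_two_by_two_sigmoid_matches_scalar_arithmetic(self):
        a = np.array([[0.5, -1.0], [2.0, 0.25]])
        b = np.array([0.1, -0.2])
        X = np.array([[1.0, 2.0], [-0.5, 0.0]])
        layer = HiddenLayer(weights=a, biases=b, activation="sig", seed=0)
        H = hidden_map(layer, X)
        for j in range(2):
            for i in range(2):
                z = a[i, 0] * X[j, 0] + a[i, 1] * X[j, 1] + b[i]
                assert H[j, i] == pytest.approx(1.0 / (1.0 + np.exp(-z)))

    @pytest.mark.parametrize("activation", ACTIVATIONS)
    def test_output_ranges(self, activation):
        layer = HiddenLayer.create(3, 20, activation, seed=4)
        X, _ = regression_problem(seed=1, n=100)
        H = hidden_map(layer, X)
        if activation in ("sig", "rbf", "hardlim"):
            assert H.min() >= 0.0 and H.max() <= 1.0
        else:
            assert H.min() >= -1.0 and H.max() <= 1.0

    def test_rbf_widths_positive(self):
        layer = HiddenLayer.create(2, 50, "rbf", seed=9)
        assert np.all(layer.biases > 0)

    def test_dimension_mismatch_is_hard_error(self):
        layer = HiddenLayer.create(3, 5, "sig", seed=0)
        with pytest.raises(LearnerError, match="dimension"):
            hidden_map(layer, np.ones((4, 2)))


class TestBatchElm:
    def test_interpolation_regime_fits_exactly(self):
        # as many neurons as (distinct) samples: training error collapses
        rng = np.random.default_rng(5)
        X = rng.uniform(-3, 3, size=(20, 2))
        y = rng.normal(size=20)
        model = fit_elm(X, y, n_hidden=20, activation="sig", seed=3)
        resid = predict(model, X) - y
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_targets_linear_in_hidden_columns_recovered(self):
        X, _ = regression_problem(seed=2, n=80)
        layer = HiddenLayer.create(3, 10, "tanh", seed=7)
        coeffs = np.arange(1.0, 11.0)
        y = hidden_map(layer, X) @ coeffs
        model = fit_elm(X, y, n_hidden=10, activation="tanh", seed=7)
        np.testing.assert_allclose(model.output_weights, coeffs, atol=1e-8)

    def test_matches_normal_equations_solve(self):
        X, y = regression_problem(seed=3, n=50)
        eps = 1e-8
        model = fit_elm(X, y, n_hidden=12, activation="sig", seed=1, ridge=eps)
        H = hidden_map(model.hidden, X)
        expected = np.linalg.solve(H.T @ H + eps * np.eye(12), H.T @ y)
        np.testing.assert_allclose(model.output_weights, expected, atol=1e-6)

    def test_least_squares_optimality_under_perturbation(self):
        X, y = regression_problem(seed=4, n=120)
        model = fit_elm(X, y, n_hidden=15, activation="sin", seed=2)
        H = hidden_map(model.hidden, X)
        sse = np.sum((H @ model.output_weights - y) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(100):
            delta = rng.normal(scale=1e-3, size=15)
            perturbed = np.sum((H @ (model.output_weights + delta) - y) ** 2)
            assert perturbed >= sse - 1e-12

    def test_non_finite_inputs_rejected(self):
        X, y = regression_problem(seed=0, n=10)
        X[0, 0] = np.nan
        with pytest.raises(LearnerError, match="non-finite"):
            fit_elm(X, y, 5)


class TestOselm:
    def test_init_on_full_set_equals_batch(self):
        X, y = regression_problem(seed=6)
        batch = fit_elm(X, y, n_hidden=12, activation="sig", seed=11)
        state = fit_oselm_init(X, y, n_hidden=12, activation="sig", seed=11)
        rel = np.linalg.norm(
            state.output_weights - batch.output_weights
        ) / np.linalg.norm(batch.output_weights)
        assert rel < 1e-8

    def test_init_chunk_of_exactly_n_hidden_samples(self):
        X, y = regression_problem(seed=7, n=10)
        state = fit_oselm_init(X, y, n_hidden=10, activation="sin", seed=5)
        assert np.all(np.isfinite(state.output_weights))
        eigvals = np.linalg.eigvalsh(state.rls_matrix)
        assert np.all(eigvals > 0)  # P0 positive definite

    def test_undersized_init_chunk_is_hard_error(self):
        X, y = regression_problem(seed=8, n=5)
        with pytest.raises(LearnerError, match="initialization block"):
            fit_oselm_init(X, y, n_hidden=10)

    def test_sequential_equals_batch(self):
        # the headline property: chunked RLS reproduces the batch solution
        X, y = regression_problem(seed=9, n=500)
        batch = fit_elm(X, y, n_hidden=25, activation="sig", seed=13)
        state = fit_oselm(X, y, n_hidden=25, activation="sig", block_size=100, seed=13)
        rel = np.linalg.norm(
            state.output_weights - batch.output_weights
        ) / np.linalg.norm(batch.output_weights)
        assert rel < 1e-6
        assert state.n_seen == 500

    def test_block_size_invariance(self):
        X, y = regression_problem(seed=10, n=400)
        one_by_one = fit_oselm(X, y, 15, "tanh", block_size=1, seed=3)
        blocked = fit_oselm(X, y, 15, "tanh", block_size=100, seed=3)
        np.testing.assert_allclose(
            one_by_one.output_weights, blocked.output_weights, rtol=1e-6, atol=1e-9
        )

    def test_empty_chunk_leaves_state_unchanged(self):
        X, y = regression_problem(seed=11, n=120)
        state = fit_oselm_init(X[:100], y[:100], n_hidden=7, activation="rbf", seed=1)
        updated = oselm_update(state, X[:0], y[:0])
        np.testing.assert_array_equal(updated.output_weights, state.output_weights)
        assert updated.n_seen == state.n_seen

    def test_init_block_bookkeeping_for_study_scale_problem(self):
        # 627-sample pool, 7 rbf neurons, block size 100 (a published setting)
        X, y = regression_problem(seed=12, n=627, d=1)
        state = fit_oselm_init(
            X[:100], y[:100], n_hidden=7, activation="rbf", block_size=100, seed=2
        )
        assert state.n_seen == 100
        assert state.block_size == 100

    def test_chunk_dimension_mismatch_is_hard_error(self):
        X, y = regression_problem(seed=13, n=150)
        state = fit_oselm_init(X, y, n_hidden=8, activation="sig", seed=0)
        with pytest.raises(LearnerError, match="dimension"):
            oselm_update(state, np.ones((5, 2)), np.ones(5))


class TestPredict:
    def test_linear_in_output_weights(self):
        X, y = regression_problem(seed=14, n=60)
        model = fit_elm(X, y, 10, "sig", seed=4)
        doubled = type(model)(
            hidden=model.hidden, output_weights=2 * model.output_weights
        )
        np.testing.assert_allclose(predict(doubled, X), 2 * predict(model, X))

    def test_deterministic_given_model_and_inputs(self):
        X, y = regression_problem(seed=15, n=60)
        model = fit_elm(X, y, 10, "rbf", seed=4)
        np.testing.assert_array_equal(predict(model, X), predict(model, X))


class TestRfBaseline:
    def test_constant_targets_predicted_exactly(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        y = np.full(50, 1234.5)
        model = fit_rf_baseline(X, y, n_trees=20, m_try=2, seed=0)
        np.testing.assert_allclose(model.predict(X), 1234.5)

    def test_seeded_reproducibility(self):
        X, y = regression_problem(seed=16, n=100)
        a = fit_rf_baseline(X, y, n_trees=30, m_try=2, seed=7).predict(X)
        b = fit_rf_baseline(X, y, n_trees=30, m_try=2, seed=7).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_m_try_capped_at_input_dimension(self):
        X, y = regression_problem(seed=17, n=50, d=1)
        model = fit_rf_baseline(X, y, n_trees=10, m_try=2, seed=0)
        assert np.all(np.isfinite(model.predict(X)))
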