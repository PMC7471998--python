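"""Objective, gradient, proximal operator and APG solver."""

import numpy as np
import pytest
from scipy.optimize import minimize

from melcbp.sparse import (
    MultiGridDesign,
    SparseModel,
    apg_solve,
    class_means,
    encode_labels,
    l21_norm,
    objective,
    prox_l21,
    ridge_solution,
    select_and_weight,
    smooth_gradient,
    smooth_objective,
    weighted_features,
)
from melcbp.synthetic import signal_design


@pytest.fixture
def small_design(rng):
    labels = np.array([1, 2, 3] * 10)
    X = [rng.standard_normal((30, 5)) for _ in range(4)]
    return MultiGridDesign(X=X, labels=labels, n_classes=3)


class TestEncodeLabels:
    def test_definition(self):
        np.testing.assert_array_equal(
            encode_labels(np.array([1, 2, 1]), 2), [[1, 0], [0, 1], [1, 0]]
        )

    def test_degenerate_class_column_empty(self):
        y = encode_labels(np.array([1, 1, 1]), 2)
        assert y[:, 1].sum() == 0

    def test_argmax_roundtrip(self, rng):
        labels = rng.integers(1, 5, size=40)
        assert np.array_equal(np.argmax(encode_labels(labels, 4), axis=1) + 1, labels)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            encode_labels(np.array([0, 1]), 2)


class TestClassMeans:
    def test_zero_weights_give_zero_means(self, small_design):
        W = np.zeros((5, 12))
        np.testing.assert_array_equal(class_means(W, small_design), 0.0)

    def test_single_sample_class_mean_is_that_sample(self, rng):
        X = [rng.standard_normal((3, 4)) for _ in range(2)]
        design = MultiGridDesign(X=X, labels=np.array([1, 2, 3]), n_classes=3)
        W = rng.standard_normal((4, 6))
        means = class_means(W, design)
        np.testing.assert_allclose(means, weighted_features(W, design))

    def test_duplicating_samples_leaves_means_unchanged(self, small_design, rng):
        W = rng.standard_normal((5, 12))
        doubled = MultiGridDesign(
            X=[np.vstack([x, x]) for x in small_design.X],
            labels=np.concatenate([small_design.labels] * 2),
            n_classes=3,
        )
        np.testing.assert_allclose(class_means(W, small_design), class_means(W, doubled))

    def test_empty_class_named_in_error(self, rng):
        design = MultiGridDesign(
            X=[rng.standard_normal((4, 3))], labels=np.array([1, 1, 2, 2]), n_classes=3
        )
        with pytest.raises(ValueError, match="class 3"):
            class_means(np.ones((3, 3)), design)


class TestObjective:
    def test_zero_weights_zero_delta_equals_label_mass(self, small_design):
        W = np.zeros((5, 12))
        # sum_i ||Y||_F^2 = beta * s for one-hot Y
        assert objective(W, small_design, 0.0, 0.0, 0.0) == pytest.approx(4 * 30)

    def test_perfect_fit_is_zero(self, rng):
        # build X so that X_i W_i = Y exactly for a known W
        W_true = rng.standard_normal((6, 4))  # two grids, c=2
        labels = np.array([1, 2] * 6)
        Y = encode_labels(labels, 2)
        X = []
        for i in range(2):
            Wi = W_true[:, 2 * i : 2 * i + 2]
            X.append(Y @ np.linalg.pinv(Wi))
        design = MultiGridDesign(X=X, labels=labels, n_classes=2)
        assert objective(W_true, design, 0.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-16)

    def test_matches_term_by_term_recomputation(self, small_design, rng):
        W = rng.standard_normal((5, 12))
        theta1, theta2, delta, eps = 0.3, 0.7, 0.2, 1e-8
        # independent recomputation with explicit loops
        fit = sum(
            np.sum((small_design.X[i] @ W[:, 3 * i : 3 * i + 3] - small_design.Y) ** 2)
            for i in range(4)
        )
        ridge = theta1 * np.sum(W**2)
        feats = np.hstack(
            [small_design.X[i] @ W[:, 3 * i : 3 * i + 3] for i in range(4)]
        )
        means = [feats[small_design.labels == u].mean(axis=0) for u in (1, 2, 3)]
        inter = delta * sum(
            1.0 / (np.sum((means[u] - means[v]) ** 2) + eps)
            for u in range(3)
            for v in range(u + 1, 3)
        )
        rows = theta2 * sum(np.linalg.norm(W[r]) for r in range(5))
        expected = fit + ridge + inter + rows
        assert objective(W, small_design, theta1, theta2, delta, eps) == pytest.approx(expected)


class TestSmoothGradient:
    def test_pure_least_squares_block_formula(self, small_design, rng):
        W = rng.standard_normal((5, 12))
        g = smooth_gradient(W, small_design, theta1=0.0, delta=0.0)
        for i in range(4):
            Xi = small_design.X[i]
            expected = 2 * Xi.T @ (Xi @ W[:, 3 * i : 3 * i + 3] - small_design.Y)
            np.testing.assert_allclose(g[:, 3 * i : 3 * i + 3], expected)

    def test_zero_at_ridge_minimizer(self, small_design):
        W = ridge_solution(small_design, 0.5)
        g = smooth_gradient(W, small_design, theta1=0.5, delta=0.0)
        assert np.abs(g).max() <= 1e-8

    def test_matches_central_finite_differences(self, small_design, rng):
        W = 0.1 * rng.standard_normal((5, 12))
        g = smooth_gradient(W, small_design, theta1=0.2, delta=0.3)
        h = 1e-6
        for _ in range(25):
            i, j = rng.integers(5), rng.integers(12)
            Wp, Wm = W.copy(), W.copy()
            Wp[i, j] += h
            Wm[i, j] -= h
            fd = (
                smooth_objective(Wp, small_design, 0.2, 0.3)
                - smooth_objective(Wm, small_design, 0.2, 0.3)
            ) / (2 * h)
            assert abs(fd - g[i, j]) <= 1e-4 * max(1.0, abs(fd))


class TestProxL21:
    def test_zero_lambda_is_identity(self, rng):
        E = rng.standard_normal((6, 4))
        np.testing.assert_array_equal(prox_l21(E, 0.0), E)

    def test_closed_form_row(self):
        out = prox_l21(np.array([[3.0, 4.0]]), 2.0)
        np.testing.assert_allclose(out, [[2.4, 3.2]])  # shrink factor 1 - 2/(2*5)

    def test_small_rows_are_annihilated(self):
        E = np.array([[0.3, 0.4], [3.0, 4.0]])
        out = prox_l21(E, 1.0)  # threshold lam/2 = 0.5 >= ||row0||
        np.testing.assert_array_equal(out[0], 0.0)
        assert np.all(out[1] != 0)

    def test_matches_numeric_minimizer(self, rng):
        E = rng.standard_normal((6, 4))
        lam = 0.8
        ours = prox_l21(E, lam)
        for r in range(6):
            res = minimize(
                lambda w, e=E[r]: np.sum((w - e) ** 2) + lam * np.linalg.norm(w),
                x0=E[r] * 0.5,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            np.testing.assert_allclose(ours[r], res.x, atol=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            prox_l21(np.ones((2, 2)), -1.0)


class TestAPGSolve:
    def test_reaches_ridge_solution_without_penalties(self, small_design):
        W_ridge = ridge_solution(small_design, 0.4)
        model = apg_solve(
            small_design,
            theta1=0.4,
            theta2=0.0,
            delta=0.0,
            init="random",
            seed=0,
            max_iter=5000,
            tol=0.0,
        )
        assert np.abs(model.W - W_ridge).max() <= 1e-4

    def test_huge_theta2_zeroes_everything(self, small_design):
        # delta=0: with the interclass term on, W=0 (coincident means) is
        # infinitely penalized and cannot be the minimizer
        model = apg_solve(small_design, theta2=1e6, delta=0.0, max_iter=50)
        np.testing.assert_array_equal(model.W, 0.0)
        assert model.selected_rows.size == 0

    def test_objective_trace_non_increasing(self):
        design, _ = signal_design(n_grids=4, n_signal=2, n_samples=30, dim=12, seed=5)
        model = apg_solve(design, max_iter=100)
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_selected_rows_non_increasing_in_theta2(self):
        design, _ = signal_design(seed=11)
        counts = [
            apg_solve(design, theta2=t2, max_iter=300).selected_rows.size
            for t2 in (0.01, 0.1, 1.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_max_iter(self, small_design):
        with pytest.raises(ValueError):
            apg_solve(small_design, max_iter=0)


class TestSelectAndWeight:
    def _model_with_weights(self, row_weights, n_grids=2, c=3):
        d = len(row_weights)
        W = np.zeros((d, n_grids * c))
        W[:, 0] = row_weights  # row norms equal the requested weights
        return SparseModel(
            W=W,
            theta1=0.1,
            theta2=0.1,
            delta=0.1,
            eps=1e-8,
            n_grids=n_grids,
            n_classes=c,
            row_weights=np.asarray(row_weights, float),
            selected_rows=np.flatnonzero(np.asarray(row_weights) > 1e-6),
            objective_trace=[0.0],
        )

    def test_unit_weights_identity(self, rng):
        model = self._model_with_weights([1.0, 1.0, 1.0])
        X = [rng.standard_normal((4, 3)) for _ in range(2)]
        out = select_and_weight(model, X)
        np.testing.assert_allclose(out, np.concatenate(X, axis=1))

    def test_zero_model_raises_helpful_error(self, rng):
        model = self._model_with_weights([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="theta2"):
            select_and_weight(model, [rng.standard_normal((4, 3))] * 2)

    def test_dimension_mismatch_rejected(self, rng):
        model = self._model_with_weights([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            select_and_weight(model, [rng.standard_normal((4, 5))] * 2)

    def test_weighting_and_subsetting(self, rng):
        model = self._model_with_weights([2.0, 0.0, 0.5])
        X = [rng.standard_normal((4, 3)) for _ in range(2)]
        out = select_and_weight(model, X)
        expected = np.concatenate(
            [x[:, [0, 2]] * np.array([2.0, 0.5]) for x in X], axis=1
        )
        np.testing.assert_allclose(out, expected)


def test_interclass_penalty_decreases_with_separation(small_design, rng):
    # scaling W scales class-mean separation; the delta term must shrink
    W = rng.standard_normal((5, 12))
    values = []
    for scale in (1.0, 2.0, 4.0):
        means = class_means(scale * W, small_design)
        term = sum(
            1.0 / (np.sum((means[u] - means[v]) ** 2) + 1e-8)
            for u in range(3)
            for v in range(u + 1, 3)
        )
        values.append(term)
    assert values[0] > values[1] > values[2]
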