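"""rMTFL: normalization, objective, proximal operator, solver, and recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from adseverity.rmtfl import (RmtflModel, SolverConfig, TaskDataset,
                              feature_scores, fit, load_task_dataset,
                              normalize_features, objective, outlier_tasks,
                              prox_group, save_task_dataset, select_features,
                              tune_lambdas)
from adseverity.synthetic import make_multitask_problem


def _model(P, Q, l1=0.0, l2=0.0):
    return RmtflModel(np.asarray(P, float), np.asarray(Q, float), l1, l2,
                      np.array([0.0]))


class TestNormalize:
    def test_unit_norm_rows(self):
        X = np.array([[3.0, 4.0], [1.0, 0.0]])
        data = TaskDataset([(X, np.zeros(2))])
        out = normalize_features(data)
        np.testing.assert_allclose(out.tasks[0][0][0], [0.6, 0.8])
        np.testing.assert_allclose(np.linalg.norm(out.tasks[0][0], axis=1), 1.0)

    def test_idempotent(self, small_multitask):
        data, _ = small_multitask
        once = normalize_features(data)
        twice = normalize_features(once)
        for (X1, _), (X2, _) in zip(once.tasks, twice.tasks):
            np.testing.assert_allclose(X1, X2, atol=1e-12)

    def test_zero_row_reported_and_untouched(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        data = TaskDataset([(X, np.zeros(2))])
        out, zero_rows = normalize_features(data, return_zero_rows=True)
        assert zero_rows == [(0, 0)]
        np.testing.assert_array_equal(out.tasks[0][0][0], [0.0, 0.0])


class TestObjective:
    def test_zero_solution_on_zero_data(self):
        X = np.ones((2, 3))
        data = TaskDataset([(X, np.zeros(3))])
        m = _model(np.zeros((2, 1)), np.zeros((2, 1)), 1.0, 1.0)
        assert objective(m, data) == 0.0

    def test_hand_evaluated_single_task(self):
        data = TaskDataset([(np.array([[1.0]]), np.array([2.0]))])
        m = _model([[1.0]], [[0.0]], l1=1.0, l2=1.0)
        # (1-2)^2 + 1*||P||_{1,2} + 0 = 2
        assert objective(m, data) == pytest.approx(2.0)

    def test_linearity_in_lambda1(self, small_multitask):
        data, _ = small_multitask
        rng = np.random.default_rng(0)
        P = rng.normal(size=(data.d, data.m))
        m1 = _model(P, np.zeros_like(P), l1=1.0)
        m2 = _model(P, np.zeros_like(P), l1=2.0)
        pen = np.linalg.norm(P, axis=1).sum()
        assert objective(m2, data) - objective(m1, data) == pytest.approx(pen, rel=1e-12)

    def test_dimension_mismatch(self, small_multitask):
        data, _ = small_multitask
        with pytest.raises(ValueError):
            objective(_model(np.zeros((3, 3)), np.zeros((3, 3))), data)


class TestProxGroup:
    def test_zero_threshold_is_identity(self, rng):
        M = rng.normal(size=(5, 4))
        np.testing.assert_array_equal(prox_group(M, 0.0, "rows"), M)

    def test_closed_form_row(self):
        np.testing.assert_allclose(prox_group(np.array([[3.0, 4.0]]), 1.0, "rows"),
                                   [[2.4, 3.2]])

    def test_full_shrinkage(self):
        M = np.array([[3.0, 4.0]])
        np.testing.assert_array_equal(prox_group(M, 5.0, "rows"), [[0.0, 0.0]])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prox_group(np.ones((2, 2)), -1.0, "rows")

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 5.0))
    def test_matches_1d_minimization_oracle(self, seed, t):
        """prox result equals argmin (1/2)||v-g||^2 + t||v||_2 along g's direction."""
        g = np.random.default_rng(seed).normal(size=6) * 3
        gn = np.linalg.norm(g)
        # the minimizer is r* g/||g|| with r* minimizing (1/2)(r-||g||)^2 + t r
        res = minimize_scalar(lambda r: 0.5 * (r - gn) ** 2 + t * r,
                              bounds=(0.0, gn + t + 1.0), method="bounded",
                              options={"xatol": 1e-12})
        expected = res.x * g / gn
        got = prox_group(g[None, :], t, "rows")[0]
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_columns_axis_transposes_rows_axis(self, rng):
        M = rng.normal(size=(4, 3))
        np.testing.assert_allclose(prox_group(M, 0.7, "columns"),
                                   prox_group(M.T, 0.7, "rows").T)


class TestFit:
    def test_huge_lambdas_shrink_everything(self, small_multitask):
        data, _ = small_multitask
        model = fit(normalize_features(data), 1e6, 1e6)
        assert np.all(model.P == 0) and np.all(model.Q == 0)

    def test_unpenalized_single_task_matches_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 60))  # d=10 features, n=60 samples
        w_true = rng.normal(size=10)
        y = X.T @ w_true
        data = TaskDataset([(X, y)])
        model = fit(data, 0.0, 0.0, SolverConfig(max_iters=5000, tolerance=1e-14))
        w_ls, *_ = np.linalg.lstsq(X.T, y, rcond=None)
        np.testing.assert_allclose(model.W[:, 0], w_ls, atol=1e-4)

    def test_objective_trace_non_increasing_over_seeds(self):
        for seed in range(20):
            data, _ = make_multitask_problem(d=15, m=3, n_per_task=25,
                                             s_shared=3, k_outlier=1,
                                             noise_sd=0.2, seed=seed)
            model = fit(normalize_features(data), 0.01, 0.01,
                        SolverConfig(max_iters=150))
            tr = model.objective_trace
            assert np.all(np.diff(tr) <= 1e-9 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_outlier_free_matches_q_frozen_solve(self):
        """With lambda2 large on an outlier-free problem, Q -> 0 and the fit
        agrees with a plain row-group multitask solve (Q frozen at zero)."""
        data, _ = make_multitask_problem(d=15, m=4, n_per_task=50, s_shared=4,
                                         k_outlier=0, noise_sd=0.05, seed=2)
        norm = normalize_features(data)
        l1 = 0.01
        joint = fit(norm, l1, 1e3, SolverConfig(max_iters=3000, tolerance=1e-13))
        assert np.all(joint.Q == 0)
        frozen = fit(norm, l1, 1e12, SolverConfig(max_iters=3000, tolerance=1e-13))
        assert objective(joint, norm) == pytest.approx(objective(frozen, norm),
                                                       abs=1e-4)

    def test_negative_lambda_rejected(self, small_multitask):
        with pytest.raises(ValueError):
            fit(small_multitask[0], -1.0, 0.0)


class TestScoresAndSelection:
    def test_zero_p_gives_zero_scores(self):
        m = _model(np.zeros((4, 3)), np.zeros((4, 3)))
        np.testing.assert_array_equal(feature_scores(m), np.zeros(4))

    def test_row_norm_closed_form_and_permutation_invariance(self):
        P = np.array([[1.0, 2.0, 2.0], [0.0, 0.0, 0.0]])
        m = _model(P, np.zeros_like(P))
        np.testing.assert_allclose(feature_scores(m), [3.0, 0.0])
        perm = _model(P[:, [2, 0, 1]], np.zeros_like(P))
        np.testing.assert_allclose(feature_scores(perm), feature_scores(m))

    def test_outlier_sets(self):
        Q = np.zeros((3, 4))
        m = _model(np.zeros_like(Q), Q)
        assert outlier_tasks(m) == set()
        Q2 = Q.copy()
        Q2[:, 2] = 5.0
        m2 = _model(np.zeros_like(Q2), Q2)
        assert outlier_tasks(m2) == {2}
        assert outlier_tasks(m2, tol=np.inf) == set()

    def test_select_features_ordering_and_ties(self):
        assert select_features(np.array([0.5, 0.9, 0.1]), 2) == [1, 0]
        assert select_features(np.array([1.0, 1.0, 0.0]), 1) == [0]
        assert select_features(np.array([0.2, 0.9, 0.5]), 3) == [1, 2, 0]
        with pytest.raises(ValueError):
            select_features(np.array([1.0, 2.0]), 3)


def test_recovery_of_planted_structure():
    """Grid-tuned fit recovers the shared support and the outlier task."""
    data, truth = make_multitask_problem(d=50, m=5, n_per_task=100, s_shared=5,
                                         k_outlier=1, noise_sd=0.1, seed=13)
    norm = normalize_features(data)
    grid = [0.001, 0.003, 0.01, 0.03, 0.1]
    l1, l2, _ = tune_lambdas(norm, grid, grid, seed=13,
                             config=SolverConfig(max_iters=300, tolerance=1e-8))
    model = fit(norm, l1, l2, SolverConfig(max_iters=500))
    assert set(select_features(feature_scores(model), 5)) == set(truth.shared_support)
    assert outlier_tasks(model, tol=0.8, relative=True) == set(truth.outlier_tasks)


def test_task_dataset_round_trip(tmp_path, small_multitask):
    data, _ = small_multitask
    save_task_dataset(data, tmp_path / "tasks")
    back = load_task_dataset(tmp_path / "tasks")
    assert back.d == data.d and back.m == data.m
    for (X1, y1), (X2, y2) in zip(data.tasks, back.tasks):
        np.testing.assert_allclose(X1, X2, atol=1e-12)
        np.testing.assert_allclose(y1, y2, atol=1e-12)
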