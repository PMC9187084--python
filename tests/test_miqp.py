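"""MIQP encoding and the exact branch-and-bound solver, cross-checked
against exhaustive enumeration."""

import numpy as np
import pytest

from boso.baselines import brute_force_best_subset
from boso.miqp import build_ols_miqp, build_ridge_miqp, choose_bigM, solve
from boso.ridge_core import make_delta_grid, ridge_fit

from conftest import make_split


class TestBuild:
    def test_cardinality_beyond_p_rejected(self, small_split):
        with pytest.raises(ValueError):
            build_ols_miqp(small_split, small_split.p + 1)
        with pytest.raises(ValueError):
            build_ridge_miqp(small_split, small_split.p + 1, [0.5])

    def test_empty_grid_rejected(self, small_split):
        with pytest.raises(ValueError):
            build_ridge_miqp(small_split, 2, [])

    def test_encoded_quantities(self, small_split):
        prob = build_ols_miqp(small_split, 2)
        Xa = np.column_stack([np.ones(small_split.n_train), small_split.X_train])
        assert np.allclose(prob.a, Xa.T @ small_split.y_train)
        assert np.allclose(prob.C, Xa.T @ Xa)
        assert np.allclose(prob.C, prob.C.T)
        assert np.all(np.linalg.eigvalsh(prob.C) > -1e-8)


class TestSolveOLS:
    def test_k_zero_is_training_mean_intercept(self, small_split):
        sol = solve(build_ols_miqp(small_split, 0))
        mu = small_split.y_train.mean()
        expected = float(np.sum((small_split.y_val - mu) ** 2))
        assert sol.objective == pytest.approx(expected)
        assert sol.beta[0] == pytest.approx(mu)
        assert sol.z.sum() == 0

    def test_k_equals_p_is_full_training_ols(self, small_split):
        sol = solve(build_ols_miqp(small_split, small_split.p))
        fit = ridge_fit(small_split.X_train, small_split.y_train, 0.0)
        r = small_split.y_val - fit.predict(small_split.X_val)
        assert sol.objective == pytest.approx(float(r @ r), rel=1e-9)
        assert sol.z.sum() == small_split.p

    def test_matches_enumeration_oracle(self):
        split = make_split(seed=21, p=6)
        sol = solve(build_ols_miqp(split, 2))
        oracle = brute_force_best_subset(split, 2, [0.0])
        assert sol.objective == pytest.approx(oracle.tuning["objective"],
                                              rel=1e-6)
        assert sol.selected == oracle.selected


class TestSolveRidge:
    def test_single_delta_support_consistency(self, small_split):
        grid = make_delta_grid(small_split.X_train, small_split.y_train, 1)
        sol = solve(build_ridge_miqp(small_split, 2, grid))
        Q = list(sol.selected)
        refit = ridge_fit(small_split.X_train[:, Q], small_split.y_train,
                          sol.delta)
        assert sol.beta[0] == pytest.approx(refit.intercept, abs=1e-6)
        assert np.allclose(sol.beta[np.array(Q) + 1], refit.coef, atol=1e-6)

    def test_matches_enumeration_over_subsets_and_grid(self):
        split = make_split(seed=5, p=6, s=3)
        grid = make_delta_grid(split.X_train, split.y_train, 3)
        sol = solve(build_ridge_miqp(split, 2, grid))
        oracle = brute_force_best_subset(split, 2, grid)
        assert sol.objective == pytest.approx(oracle.tuning["objective"],
                                              rel=1e-6)

    def test_tiny_delta_approaches_ols_objective(self):
        split = make_split(seed=13, p=5, s=2, snr=50.0)
        sol_ols = solve(build_ols_miqp(split, 2))
        sol_ridge = solve(build_ridge_miqp(split, 2, [1e-10]))
        assert sol_ridge.objective == pytest.approx(sol_ols.objective,
                                                    rel=1e-5)

    def test_constraint_feasibility(self, small_split):
        grid = make_delta_grid(small_split.X_train, small_split.y_train, 3)
        sol = solve(build_ridge_miqp(small_split, 3, grid))
        assert sol.z.sum() == 3
        assert 0 <= sol.t_selected < 3
        # deselected coefficients are exactly zero
        off = np.flatnonzero(sol.z == 0) + 1
        assert np.all(sol.beta[off] == 0.0)


class TestBigM:
    def test_scales_with_response(self, small_split):
        # beta and a scale linearly with y; compare two scalings large
        # enough that the absolute floor is inactive
        from boso.data import SplitData

        grid = [0.5, 5.0]
        s1 = SplitData(small_split.X_train, 1e3 * small_split.y_train,
                       small_split.X_val, 1e3 * small_split.y_val)
        s2 = SplitData(small_split.X_train, 1e4 * small_split.y_train,
                       small_split.X_val, 1e4 * small_split.y_val)
        assert choose_bigM(s2, grid) == pytest.approx(
            10 * choose_bigM(s1, grid))

    def test_covers_full_model_coefficients(self, small_split):
        grid = make_delta_grid(small_split.X_train, small_split.y_train, 4)
        M = choose_bigM(small_split, grid)
        for delta in grid:
            fit = ridge_fit(small_split.X_train, small_split.y_train, delta)
            assert M >= 10 * np.max(np.abs(fit.beta))

    def test_bigm_mode_agrees_with_indicator_mode(self):
        split = make_split(seed=31, p=6)
        grid = make_delta_grid(split.X_train, split.y_train, 2)
        prob = build_ridge_miqp(split, 2, grid)
        a = solve(prob, use_indicator=True)
        b = solve(prob, use_indicator=False)
        assert a.objective == pytest.approx(b.objective, rel=1e-9)

    def test_inflating_m_tenfold_leaves_optimum_unchanged(self):
        split = make_split(seed=32, p=6)
        grid = make_delta_grid(split.X_train, split.y_train, 2)
        base = build_ridge_miqp(split, 2, grid)
        inflated = build_ridge_miqp(split, 2, grid, bigM=10 * base.bigM)
        a = solve(base, use_indicator=False)
        b = solve(inflated, use_indicator=False)
        assert a.objective == pytest.approx(b.objective, rel=1e-6)


class TestSearchBehaviour:
    def test_time_limit_returns_incumbent(self):
        split = make_split(seed=3, p=12, s=4, n_train=40, n_val=40)
        grid = make_delta_grid(split.X_train, split.y_train, 2)
        sol = solve(build_ridge_miqp(split, 4, grid), time_limit_s=1e-9)
        assert sol.status == "feasible_time_limit"
        assert sol.z.sum() == 4 and np.isfinite(sol.objective)

    def test_validation_sse_nonincreasing_in_k_noiseless(self):
        # with a noiseless response the training fit is exact, so adding
        # features can never hurt the validation error
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 6))
        beta = np.array([1.0, 0, 0, -2.0, 0, 0])
        y = X @ beta
        from boso.data import SplitData

        split = SplitData(X[:20], y[:20], X[20:], y[20:])
        objs = [solve(build_ols_miqp(split, K)).objective for K in range(7)]
        assert all(a >= b - 1e-8 for a, b in zip(objs, objs[1:]))

    def test_deterministic_given_identical_problem(self):
        split = make_split(seed=17, p=7, s=3)
        grid = make_delta_grid(split.X_train, split.y_train, 3)
        a = solve(build_ridge_miqp(split, 3, grid))
        b = solve(build_ridge_miqp(split, 3, grid))
        assert a.selected == b.selected and a.objective == b.objective
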