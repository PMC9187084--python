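"""Cardinality sweep, random-block decomposition and the end-to-end driver."""

import numpy as np
import pytest

from boso.data import SplitData, train_val_split
from boso.driver import (
    BosoConfig,
    block_stage,
    boso,
    k_sweep,
    random_blocks,
)
from boso.ridge_core import make_delta_grid
from boso.sim_bench import SimulationSpec, simulate

from conftest import make_split


def _noise_split(seed=0, n=400, p=5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return SplitData(X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :])


class TestKSweep:
    def test_pure_noise_keeps_intercept_only(self):
        split = _noise_split(seed=1)
        grid = make_delta_grid(split.X_train, split.y_train, 5)
        fit = k_sweep(split, grid, BosoConfig(seed=1), criterion="bic")
        assert fit.K == 0 and fit.selected == ()

    def test_noiseless_two_feature_recovery(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 8))
        y = 2.0 * X[:, 1] - 1.5 * X[:, 6]
        split = SplitData(X[:20], y[:20], X[20:], y[20:])
        grid = make_delta_grid(X, y, 3)
        fit = k_sweep(split, grid, BosoConfig(seed=2), criterion="bic")
        assert fit.selected == (1, 6)
        traj = dict(fit.ic_trajectory)
        assert min(traj, key=traj.get) == 2

    def test_returned_fit_minimizes_trajectory(self, small_split):
        grid = make_delta_grid(small_split.X_train, small_split.y_train, 3)
        fit = k_sweep(small_split, grid, BosoConfig(seed=3), criterion="bic")
        values = [v for _, v in fit.ic_trajectory]
        assert fit.ic_value == min(values)


class TestRandomBlocks:
    def test_block_sizes(self, rng):
        blocks = random_blocks(range(7), 3, rng)
        assert sorted(len(b) for b in blocks) == [1, 3, 3]
        assert sorted(j for b in blocks for j in b) == list(range(7))

    def test_small_input_single_block(self, rng):
        assert len(random_blocks(range(3), 5, rng)) == 1

    def test_seeded_determinism(self):
        a = random_blocks(range(20), 6, np.random.default_rng(4))
        b = random_blocks(range(20), 6, np.random.default_rng(4))
        assert a == b

    def test_degenerate_length_rejected(self, rng):
        with pytest.raises(ValueError):
            random_blocks(range(5), 1, rng)


class TestBlockStage:
    def test_small_candidate_set_is_single_sweep(self):
        split = make_split(seed=6, p=6, s=2, snr=6.0)
        cfg = BosoConfig(seed=6)
        res = block_stage(split, range(6), cfg, "bic", 5,
                          rng=np.random.default_rng(6))
        assert res.n_iters == 0 and res.converged
        grid = make_delta_grid(
            np.vstack([split.X_train, split.X_val]),
            np.concatenate([split.y_train, split.y_val]), 5)
        direct = k_sweep(split, grid, cfg, criterion="bic")
        assert tuple(sorted(res.selected)) == direct.selected

    def test_all_noise_candidates_mostly_eliminated(self):
        split = _noise_split(seed=7, n=400, p=25)
        cfg = BosoConfig(seed=7, block_size=10)
        res = block_stage(split, range(25), cfg, "bic", 5,
                          rng=np.random.default_rng(7))
        assert len(res.selected) <= 2

    def test_survivors_shrink_only(self):
        spec = SimulationSpec(n=120, p=24, s=4, snr=4.0, seed=8)
        data = simulate(spec)
        split = train_val_split(data.X, data.y, seed=8)
        cfg = BosoConfig(seed=8, block_size=8)
        res = block_stage(split, range(24), cfg, "bic", 5,
                          rng=np.random.default_rng(8))
        assert set(res.selected) <= set(range(24))
        for entry in res.log:
            assert set(entry["selected"]) <= set(entry["block_features"])


class TestBoso:
    def test_bic_run_is_single_stage(self):
        spec = SimulationSpec(n=80, p=10, s=3, snr=4.0, seed=9)
        data = simulate(spec)
        fit = boso(data.X, data.y, BosoConfig(seed=9, criterion="bic"))
        assert all(e["stage"] == 1 for e in fit.stage_log)

    def test_ebic_stage2_restricted_to_stage1_survivors(self):
        spec = SimulationSpec(n=100, p=30, s=5, snr=4.0, seed=10)
        data = simulate(spec)
        fit = boso(data.X, data.y, BosoConfig(seed=10, criterion="ebic"))
        stage1 = {j for e in fit.stage_log if e["stage"] == 1
                  for j in e["selected"]}
        stage2_entries = [e for e in fit.stage_log if e["stage"] == 2]
        if stage2_entries:  # stage 2 runs only when stage 1 kept something
            stage2_candidates = {
                j for e in stage2_entries for j in e.get("block_features", ())
            }
            assert stage2_candidates <= stage1
        assert set(fit.selected) <= stage1

    def test_strong_signal_low_setting_recovery(self):
        spec = SimulationSpec(n=100, p=10, s=5, snr=6.0, seed=11)
        data = simulate(spec)
        fit = boso(data.X, data.y, BosoConfig(seed=11))
        assert fit.selected == tuple(np.flatnonzero(data.beta_true))

    def test_duplicate_column_selects_exactly_one_of_pair(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((80, 5))
        y = 3.0 * X[:, 2] + 0.1 * rng.standard_normal(80)
        X_dup = np.column_stack([X, X[:, 2]])  # column 5 duplicates column 2
        fit = boso(X_dup, y, BosoConfig(seed=12))
        assert len({2, 5} & set(fit.selected)) == 1

    def test_seeded_determinism_end_to_end(self):
        spec = SimulationSpec(n=60, p=12, s=3, snr=3.0, seed=13)
        data = simulate(spec)
        cfg = dict(seed=13, criterion="ebic")
        a = boso(data.X, data.y, BosoConfig(**cfg))
        b = boso(data.X, data.y, BosoConfig(**cfg))
        assert a.selected == b.selected
        assert np.array_equal(a.beta, b.beta)
        assert a.ic_trajectory == b.ic_trajectory

    def test_back_transformed_model_predicts_on_original_scale(self):
        spec = SimulationSpec(n=100, p=8, s=2, snr=50.0, seed=14)
        data = simulate(spec)
        X = data.X * 13.0 + 7.0  # shift/scale the features
        fit = boso(X, data.y, BosoConfig(seed=14))
        r = data.y - fit.predict(X)
        assert np.mean(r**2) < 0.2 * np.var(data.y)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            boso(np.ones((3, 2)), np.ones(3), BosoConfig(seed=1))
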