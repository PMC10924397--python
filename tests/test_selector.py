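"""Orchestration: splitting, the elimination loop, and run-level invariants."""

import numpy as np
import pytest

import scfsnn.selector as selector_mod
from scfsnn import (
    Labels,
    NetConfig,
    RunConfig,
    SimParams,
    run_scfsnn,
    simulate_counts,
    split_data,
)


def fast_cfg(seed=0, **kw):
    """Small network for test speed; protocol constants untouched."""
    net = NetConfig(hidden_sizes=(32, 16), init_epochs=15, step_epochs=2)
    return RunConfig(net=net, seed=seed, **kw)


@pytest.fixture(scope="module")
def sim_small():
    return simulate_counts(SimParams(n_cells=160, n_genes=150, de_prop=0.2, seed=21))


@pytest.fixture(scope="module")
def result_small(sim_small):
    cfg = fast_cfg(seed=3)
    return run_scfsnn(sim_small.counts, sim_small.labels, cfg), cfg


class TestSplitData:
    def test_sizes_64_16_20(self):
        y = Labels(np.repeat([0, 1], 50), 2)
        tr, va, te = split_data(100, (0.64, 0.16, 0.20), 0, y)
        assert (len(tr), len(va), len(te)) == (64, 16, 20)

    def test_partition_disjoint_and_covering(self):
        y = Labels(np.repeat([0, 1, 2], [30, 20, 13]), 3)
        tr, va, te = split_data(63, (0.64, 0.16, 0.20), 5, y)
        allidx = np.concatenate([tr, va, te])
        assert len(allidx) == 63
        assert len(np.unique(allidx)) == 63

    def test_stratification_every_class_everywhere(self):
        y = Labels(np.repeat([0, 1, 2], [40, 12, 8]), 3)
        tr, va, te = split_data(60, (0.64, 0.16, 0.20), 1, y)
        for idx in (tr, va, te):
            assert set(y.y[idx]) == {0, 1, 2}

    def test_seed_determinism(self):
        y = Labels(np.repeat([0, 1], 30), 2)
        a = split_data(60, (0.64, 0.16, 0.20), 7, y)
        b = split_data(60, (0.64, 0.16, 0.20), 7, y)
        c = split_data(60, (0.64, 0.16, 0.20), 8, y)
        for x, z in zip(a, b):
            np.testing.assert_array_equal(x, z)
        assert any(not np.array_equal(x, z) for x, z in zip(a, c))

    def test_tiny_class_rejected(self):
        y = Labels(np.array([0] * 58 + [1, 1]), 2)
        with pytest.raises(ValueError, match="class 1"):
            split_data(60, (0.64, 0.16, 0.20), 0, y)


class TestRunInvariants:
    def test_selected_genes_subset_of_input(self, sim_small, result_small):
        res, _ = result_small
        assert set(res.selected_gene_ids) <= set(sim_small.counts.gene_ids.tolist())
        assert len(res.selected_gene_ids) >= 1

    def test_active_features_strictly_decreasing(self, result_small):
        res, _ = result_small
        r = res.trajectory["r"].to_numpy()
        assert np.all(np.diff(r) < 0) or len(r) == 1

    def test_final_eta_at_or_below_target(self, result_small):
        res, cfg = result_small
        if not res.stopped_by_safeguard:
            assert res.trajectory["eta_hat"].iloc[-1] <= cfg.eta_star

    def test_full_run_reproducibility(self, sim_small):
        a = run_scfsnn(sim_small.counts, sim_small.labels, fast_cfg(seed=5))
        b = run_scfsnn(sim_small.counts, sim_small.labels, fast_cfg(seed=5))
        assert a.selected_gene_ids == b.selected_gene_ids
        assert a.final_test_accuracy == b.final_test_accuracy
        assert a.trajectory.equals(b.trajectory)

    def test_test_cells_only_touched_after_selection(self, sim_small, monkeypatch):
        """The 20% test block enters exactly one normalization call, after the loop."""
        calls = []
        real = selector_mod.apply_normalize

        def spy(counts, fitted):
            calls.append(counts.n_cells)
            return real(counts, fitted)

        monkeypatch.setattr(selector_mod, "apply_normalize", spy)
        res = run_scfsnn(sim_small.counts, sim_small.labels, fast_cfg(seed=2))
        n = sim_small.counts.n_cells
        n_te = round(0.2 * n)
        assert calls.count(n_te) == 1
        assert calls[-1] == n_te  # the test block is the last normalization
        assert 0.0 <= res.final_test_accuracy <= 1.0

    def test_max_steps_safeguard_records_abort(self, sim_small):
        res = run_scfsnn(sim_small.counts, sim_small.labels, fast_cfg(seed=1, max_steps=2))
        assert res.stopped_by_safeguard
        assert res.n_steps <= 3


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RunConfig(train_frac=0.5, val_frac=0.2, test_frac=0.2)

    def test_bad_p0_mode(self):
        with pytest.raises(ValueError, match="p0_mode"):
            RunConfig(p0_mode="wild")
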