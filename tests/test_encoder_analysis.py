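"""Encoder attention statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_entropy, brute_force_spike_weights
from retinattn.encoder_analysis import (
    EncoderAttentionSet,
    WindowAttention,
    compare_physiology,
    consensus_units,
    encoder_entropy,
    head_divergence,
    kde_grid,
    spike_weights,
    topk_at_threshold,
    unit_importance,
)


def attention_set(attn_list, unit_indices_list, roster):
    windows = [
        WindowAttention(i, float(i + 1), a, u, np.linspace(i, i + 1, a.shape[-1]))
        for i, (a, u) in enumerate(zip(attn_list, unit_indices_list))
    ]
    h, latents, _ = attn_list[0].shape
    return EncoderAttentionSet(windows, h, latents, roster=roster)


def random_row_stochastic(h, latents, n, seed=0):
    a = np.random.default_rng(seed).random((h, latents, n))
    return a / a.sum(axis=-1, keepdims=True)


class TestSpikeWeights:
    def test_uniform_attention_gives_uniform_weights(self):
        n = 6
        a = np.full((2, 4, n), 1.0 / n)
        sw = spike_weights(attention_set([a], [np.zeros(n, dtype=int)], [0]))
        assert np.allclose(sw.wbar[0], 1.0 / n)
        assert np.allclose(sw.what[0], 1.0)

    def test_one_hot_attention(self):
        a = np.zeros((1, 4, 5))
        a[:, :, 3] = 1.0
        sw = spike_weights(attention_set([a], [np.zeros(5, dtype=int)], [0]))
        assert np.allclose(sw.wbar[0][0], [0, 0, 0, 1, 0])
        assert sw.what[0][0, 3] == pytest.approx(5.0)

    def test_matches_brute_force_summation(self, fixtures):
        a = fixtures["toy_attention"]  # (1, 4, 5) row-stochastic
        sw = spike_weights(attention_set([a], [np.arange(5)], list(range(5))))
        ref_wbar, ref_what = brute_force_spike_weights(a)
        assert np.abs(sw.wbar[0] - ref_wbar).max() < 1e-10
        assert np.abs(sw.what[0] - ref_what).max() < 1e-10

    def test_normalization_invariants(self):
        a = random_row_stochastic(3, 8, 17, seed=5)
        sw = spike_weights(attention_set([a], [np.zeros(17, dtype=int)], [0]))
        assert np.allclose(sw.wbar[0].sum(axis=1), 1.0)
        assert np.allclose(sw.what[0].mean(axis=1), 1.0)


class TestEncoderEntropy:
    def test_one_hot_is_zero(self):
        a = np.zeros((1, 4, 5))
        a[:, :, 2] = 1.0
        ent = encoder_entropy(spike_weights(
            attention_set([a], [np.zeros(5, dtype=int)], [0])))
        assert ent["E_nats"].iloc[0] == 0.0

    def test_uniform_is_log_n(self):
        n = 100
        a = np.full((1, 4, n), 1.0 / n)
        ent = encoder_entropy(spike_weights(
            attention_set([a], [np.zeros(n, dtype=int)], [0])))
        assert ent["E_nats"].iloc[0] == pytest.approx(np.log(100))

    def test_hand_computed_value(self):
        # w̄ = (0.5, 0.25, 0.25) -> 1.5 ln 2 = 1.0397
        a = np.tile(np.array([0.5, 0.25, 0.25]), (1, 4, 1))
        ent = encoder_entropy(spike_weights(
            attention_set([a], [np.zeros(3, dtype=int)], [0])))
        assert ent["E_nats"].iloc[0] == pytest.approx(1.0397, abs=1e-4)

    def test_matches_brute_force_and_bounds(self):
        a = random_row_stochastic(4, 8, 23, seed=9)
        sw = spike_weights(attention_set([a], [np.zeros(23, dtype=int)], [0]))
        ent = encoder_entropy(sw)
        ref = brute_force_entropy(sw.wbar[0])
        assert np.abs(np.sort(ent["E_nats"].to_numpy()) - np.sort(ref)).max() < 1e-10
        assert ((ent["E_nats"] >= 0) & (ent["E_nats"] <= np.log(23))).all()

    def test_timestamped_at_window_end(self):
        a = random_row_stochastic(1, 4, 5)
        ent = encoder_entropy(spike_weights(
            attention_set([a, a], [np.zeros(5, dtype=int)] * 2, [0])))
        assert sorted(ent["t_s"].unique()) == [1.0, 2.0]


class TestHeadDivergence:
    @staticmethod
    def _entropy_frame(samples_per_head):
        rows = []
        for h, samples in enumerate(samples_per_head):
            rows += [{"t_s": float(i), "head": h, "E_nats": float(e)}
                     for i, e in enumerate(samples)]
        return pd.DataFrame(rows)

    def test_identical_heads_d_zero_p_one(self):
        s = np.array([1.0, 2.0, 3.0])
        div = head_divergence(self._entropy_frame([s, s]))
        assert div["D"][0, 1] == 0.0
        assert div["p"][0, 1] == pytest.approx(1.0)

    def test_well_separated_distributions(self):
        rng = np.random.default_rng(0)
        div = head_divergence(self._entropy_frame(
            [rng.normal(0, 1, 100), rng.normal(5, 1, 100)]))
        assert div["p"][0, 1] < 1e-9

    def test_matrix_symmetric_diagonal_undefined(self):
        rng = np.random.default_rng(1)
        div = head_divergence(self._entropy_frame(
            [rng.normal(size=30) for _ in range(4)]))
        assert np.allclose(div["D"], div["D"].T, equal_nan=True)
        assert np.isnan(np.diag(div["D"])).all()
        off = ~np.eye(4, dtype=bool)
        assert (div["p_bonferroni"][off] >= div["p"][off] - 1e-15).all()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            head_divergence(self._entropy_frame([[1.0], [2.0]]))


class TestUnitImportance:
    def test_toy_hand_example(self, fixtures):
        """H=1, W=1: unit A spikes w̄={0.4,0.4}, unit B {0.2} -> I=0.4, 0.2."""
        toy = fixtures["importance_toy"]
        a = np.tile(toy["wbar"][None], (1, 4, 1))  # 4 latents, same rows
        sw = spike_weights(attention_set([a], [toy["unit_indices"]], [0, 1]))
        ranking = unit_importance(sw)
        by_id = ranking.set_index("unit_id")["importance"]
        assert by_id[0] == pytest.approx(toy["expected"][0])
        assert by_id[1] == pytest.approx(toy["expected"][1])
        assert ranking["unit_id"].iloc[0] == 0

    def test_uniform_attention_equal_importance(self):
        n = 12
        a = np.full((2, 4, n), 1.0 / n)
        units = np.repeat(np.arange(4), 3)
        ranking = unit_importance(spike_weights(
            attention_set([a], [units], list(range(4)))))
        assert np.allclose(ranking["importance"], 1.0 / n)

    def test_brute_force_triple_sum(self):
        """Mean over heads and spike-containing windows of per-spike means."""
        rng = np.random.default_rng(3)
        attn, idx = [], []
        roster = [0, 1, 2]
        for _ in range(3):
            n = rng.integers(4, 9)
            attn.append(random_row_stochastic(2, 5, n, seed=rng.integers(99)))
            idx.append(rng.integers(0, 3, n))
        sw = spike_weights(attention_set(attn, idx, roster))
        ranking = unit_importance(sw).set_index("unit_id")["importance"]
        for u in roster:
            vals = []
            for a, units in zip(attn, idx):
                mask = units == u
                if not mask.any():
                    continue
                wbar = a.mean(axis=1)
                for h in range(2):
                    vals.append(wbar[h, mask].mean())
            assert ranking[u] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_importance_independent_of_firing_rate(self):
        """Equal per-spike weight => equal I(u) regardless of spike count."""
        a = np.array([[[0.2, 0.2, 0.2, 0.2, 0.2]]])
        sw = spike_weights(attention_set([a], [np.array([0, 0, 0, 0, 1])], [0, 1]))
        imp = unit_importance(sw).set_index("unit_id")["importance"]
        assert imp[0] == pytest.approx(imp[1])  # 4 spikes vs 1 spike

    def test_zero_spike_unit_ranked_last(self):
        a = np.array([[[0.5, 0.5]]])
        ranking = unit_importance(spike_weights(
            attention_set([a], [np.array([0, 1])], [0, 1, 2])))
        assert np.isnan(ranking.set_index("unit_id")["importance"][2])
        assert ranking["unit_id"].iloc[-1] == 2


class TestAblationHelpers:
    def test_topk_first_crossing(self):
        curve = pd.DataFrame({"n_removed": [0, 1, 2, 3],
                              "r2": [0.9, 0.6, 0.45, 0.2]})
        res = topk_at_threshold(curve, 0.5)
        assert res == {"k": 2, "crossed": True}

    def test_topk_never_crossed_flagged(self):
        curve = pd.DataFrame({"n_removed": [0, 1, 2], "r2": [0.9, 0.8, 0.7]})
        res = topk_at_threshold(curve, 0.5)
        assert res["crossed"] is False and res["k"] == 2

    def test_topk_failed_before_ablation(self):
        curve = pd.DataFrame({"n_removed": [0, 1], "r2": [0.4, 0.2]})
        assert topk_at_threshold(curve, 0.5)["k"] == 0

    def test_consensus_majority_rule(self):
        lists = [[1, 2], [1, 3], [1, 2], [2, 4], [1, 2], [5, 2], [1, 6], [1, 2]]
        res = consensus_units(lists, min_fraction=0.5)
        # unit 1 in 6/8, unit 2 in 6/8, others below 4
        assert res["consensus"] == [1, 2]

    def test_consensus_exact_half_included(self):
        lists = [[1], [1], [2], [3], [1], [1], [4], [5]]
        res = consensus_units(lists, 0.5)
        assert res["consensus"] == [1]  # 4 of 8 = exactly half

    def test_consensus_identical_lists(self):
        res = consensus_units([[7, 8, 9]] * 4)
        assert res["consensus"] == [7, 8, 9]

    def test_consensus_needs_two_seeds(self):
        with pytest.raises(ValueError):
            consensus_units([[1]])


class TestAblationExperiment:
    def test_step_zero_is_unablated_r2(self, tiny_trained_decoder):
        dec, ds, _ = tiny_trained_decoder
        test_w = ds.split("test")
        from retinattn.encoder_analysis import (
            ablation_experiment,
            collect_encoder_attention,
        )
        ranking = unit_importance(spike_weights(
            collect_encoder_attention(dec, ds.windows)))
        curve = ablation_experiment(dec, test_w, ranking, "attention", step=10)
        r2_0 = dec.evaluate_r2(test_w)["r2"]
        assert curve.loc[curve["n_removed"] == 0, "r2"].iloc[0] == pytest.approx(r2_0)
        assert curve["n_removed"].max() == len(ds.roster)

    def test_random_strategy_produces_iterations(self, tiny_trained_decoder):
        dec, ds, _ = tiny_trained_decoder
        from retinattn.encoder_analysis import (
            ablation_experiment,
            collect_encoder_attention,
        )
        ranking = unit_importance(spike_weights(
            collect_encoder_attention(dec, ds.windows)))
        curve = ablation_experiment(dec, ds.split("test"), ranking, "random",
                                    n_random_iters=3, step=15)
        assert curve["iter"].nunique() == 3


class TestPhysiologyComparison:
    @staticmethod
    def _phys(n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "unit_id": np.arange(n),
            "fbr": rng.uniform(-1, 1, n),
            "sustain_index": rng.uniform(0, 1, n),
            "latency_s": rng.uniform(0, 0.5, n),
            "mean_rate_hz": rng.gamma(3, 2, n),
        })

    def test_subset_equal_population_d_zero(self):
        phys = self._phys()
        res = compare_physiology(list(range(60)), phys)
        assert (res["D"] == 0).all()
        assert np.allclose(res["p"], 1.0)

    def test_planted_high_rate_subset_detected(self):
        phys = self._phys(120)
        phys.loc[:49, "mean_rate_hz"] += 15.0
        res = compare_physiology(list(range(50)), phys,
                                 other_ids=list(range(50, 120)))
        rate_p = res.loc[res["feature"] == "mean_rate_hz", "p"].iloc[0]
        assert rate_p < 0.05

    def test_identical_hand_samples_d_zero(self):
        from scipy.stats import ks_2samp

        assert ks_2samp([0, 1], [0, 1]).statistic == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_physiology([999], self._phys())

    def test_kde_grid_shapes_and_mass(self):
        phys = self._phys()
        grid = kde_grid(phys, "fbr", "mean_rate_hz", n_grid=20)
        assert grid["density"].shape == (20, 20)
        assert (grid["density"] >= 0).all()
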