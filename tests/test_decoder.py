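"""Tokenization, model forward contracts, training, splits, and the OLE."""

import dataclasses

import numpy as np
import pytest

import retinattn as r
from retinattn import decoding
from retinattn.decoding import (
    ContextWindow,
    _lr_at,
    build_dataset,
    fit_ole,
    r2_score_columns,
    tokenize,
)
from retinattn.model import SpikeDecoderNet
from retinattn.synthetic import SpikeEventTable


def make_net(n_units=6, out_dim=1, **overrides):
    cfg = r.ModelConfig.scaled_down(latent_dim=32, n_latents=8, depth=1,
                                    n_heads=2, head_dim=8, **overrides)
    return SpikeDecoderNet(cfg, n_units=n_units, out_dim=out_dim, rng_seed=0), cfg


class TestTokenize:
    def test_one_token_per_spike(self):
        times = np.sort(np.random.default_rng(0).uniform(0, 10, 37))
        table = SpikeEventTable.from_arrays(np.zeros(37, dtype=int), times,
                                            roster=[0], duration=10.0)
        ids, rel = tokenize(table, 2.0, 1.0, {0: 0})
        in_window = ((times >= 2.0) & (times < 3.0)).sum()
        assert len(ids) == in_window
        assert (rel >= 0).all() and (rel < 1.0).all()

    def test_unknown_unit_rejected(self):
        table = SpikeEventTable.from_arrays(np.array([3]), np.array([0.5]),
                                            roster=[3], duration=1.0)
        with pytest.raises(KeyError):
            tokenize(table, 0.0, 1.0, {0: 0})


class TestForward:
    def test_attention_rows_sum_to_one_and_shapes(self):
        net, cfg = make_net()
        ids = np.array([0, 1, 2, 2, 5, 4, 3])
        times = np.linspace(0.05, 0.95, 7)
        out_times = np.linspace(0.05, 0.95, 10)
        out = net.forward(ids, times, out_times, capture_attention=True)
        assert out.data.shape == (10, 1)
        assert np.isfinite(out.data).all()
        enc = net.encoder_attention
        dec = net.decoder_attention
        assert enc.shape == (cfg.n_heads, cfg.n_latents, 7)
        assert dec.shape == (cfg.n_heads, 10, cfg.n_latents)
        assert np.allclose(enc.sum(axis=-1), 1.0, atol=1e-5)
        assert np.allclose(dec.sum(axis=-1), 1.0, atol=1e-5)

    def test_token_order_permutation_invariance(self):
        """The encoder is set-structured: time enters only via encodings."""
        net, _ = make_net()
        rng = np.random.default_rng(1)
        ids = rng.integers(0, 6, 20)
        times = rng.uniform(0, 1, 20)
        out_times = np.array([0.25, 0.75])
        a = net.forward(ids, times, out_times).data
        perm = rng.permutation(20)
        b = net.forward(ids[perm], times[perm], out_times).data
        assert np.allclose(a, b, atol=1e-10)

    def test_empty_window_rejected(self):
        net, _ = make_net()
        with pytest.raises(ValueError):
            net.forward(np.array([], dtype=int), np.array([]), np.array([0.5]))

    def test_unknown_unit_rejected(self):
        net, _ = make_net(n_units=4)
        with pytest.raises(ValueError):
            net.forward(np.array([7]), np.array([0.5]), np.array([0.5]))

    def test_same_unit_different_times_differ_only_in_time_code(self):
        from retinattn.nn import sinusoidal_time_encoding

        enc = sinusoidal_time_encoding(np.array([0.2, 0.8]), 32)
        assert not np.allclose(enc[0], enc[1])


class TestR2:
    def test_perfect_prediction(self):
        y = np.random.default_rng(0).normal(size=(50, 2))
        assert np.allclose(r2_score_columns(y, y), 1.0)

    def test_mean_prediction_is_zero(self):
        y = np.random.default_rng(0).normal(size=(50, 1))
        pred = np.full_like(y, y.mean())
        assert r2_score_columns(y, pred)[0] == pytest.approx(0.0, abs=1e-12)

    def test_small_noise_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(20000, 1))
        pred = y + 0.1 * y.std() * rng.normal(size=y.shape)
        assert r2_score_columns(y, pred)[0] == pytest.approx(0.99, abs=0.005)

    def test_zero_variance_target_flagged(self):
        y = np.ones((10, 1))
        assert np.isnan(r2_score_columns(y, y)[0])


class TestSplits:
    def test_block_split_no_window_spans_boundary(self, flash_stim,
                                                  small_flash_session):
        _, spikes = small_flash_session
        mcfg = r.ModelConfig.scaled_down()
        tcfg = r.TrainConfig.scaled_down(rng_seed=3)
        ds = build_dataset(spikes, flash_stim, mcfg, tcfg)
        block = ds.meta["block_len"]
        starts = {}
        for w in ds.windows:
            b = int(w.start // block)
            assert w.start + ds.window_len <= (b + 1) * block + 1e-9
            starts.setdefault(b, set()).add(w.split)
        # every block belongs to exactly one split
        assert all(len(s) == 1 for s in starts.values())

    def test_split_fractions_roughly_respected(self, flash_stim,
                                               small_flash_session):
        _, spikes = small_flash_session
        ds = build_dataset(spikes, flash_stim, r.ModelConfig.scaled_down(),
                           r.TrainConfig.scaled_down())
        n = len(ds.windows)
        assert len(ds.split("train")) / n == pytest.approx(0.7, abs=0.15)
        assert len(ds.split("test")) >= 1 and len(ds.split("val")) >= 1

    def test_invalid_split_fractions_rejected(self):
        with pytest.raises(ValueError):
            r.TrainConfig(split=(0.5, 0.2, 0.2))


class TestTraining:
    def test_lr_decays_by_factor_over_final_quarter(self):
        cfg = r.TrainConfig(lr=1e-3, epochs=100, lr_decay_factor=0.1)
        assert _lr_at(0, cfg) == 1e-3
        assert _lr_at(74, cfg) == 1e-3
        assert _lr_at(99, cfg) == pytest.approx(1e-4)

    def test_same_seed_identical_curves(self, flash_stim, small_flash_session):
        _, spikes = small_flash_session
        mcfg = r.ModelConfig.scaled_down(latent_dim=32, n_latents=8, depth=1,
                                         n_heads=2, head_dim=8, output_rate=10.0)
        tcfg = r.TrainConfig.scaled_down(epochs=2, rng_seed=5)
        ds = build_dataset(spikes, flash_stim, mcfg, tcfg)
        _, c1 = decoding.train(ds, mcfg, tcfg)
        _, c2 = decoding.train(ds, mcfg, tcfg)
        assert np.allclose(c1["train_loss"], c2["train_loss"])

    def test_loss_decreases_and_decoder_predicts(self, tiny_trained_decoder):
        dec, ds, curve = tiny_trained_decoder
        assert curve["train_loss"].iloc[-1] < curve["train_loss"].iloc[0]
        res = dec.evaluate_r2(ds.split("test"))
        assert np.isfinite(res["r2"])

    def test_prediction_clipped_to_training_range(self, tiny_trained_decoder):
        dec, ds, _ = tiny_trained_decoder
        for w in ds.split("test"):
            p = dec.predict(w)
            assert (p >= dec.target_lo - 1e-12).all()
            assert (p <= dec.target_hi + 1e-12).all()

    def test_excluding_all_units_predicts_chance(self, tiny_trained_decoder):
        dec, ds, _ = tiny_trained_decoder
        w = ds.split("test")[0]
        p = dec.predict(w, exclude_units=set(range(len(ds.roster))))
        assert np.allclose(p, dec.target_mean)


class TestFinetune:
    def test_core_copied_embeddings_fresh(self, tiny_trained_decoder):
        dec, _, _ = tiny_trained_decoder
        new = dec.net.spawn_for_new_session(n_units=9, rng_seed=1)
        assert new.unit_emb.data.shape[0] == 9
        old_core = dec.net.core_parameters()
        new_core = new.core_parameters()
        assert all(np.array_equal(a.data, b.data)
                   for a, b in zip(old_core, new_core))

    def test_frozen_core_updates_only_embeddings(self, flash_stim,
                                                 tiny_trained_decoder):
        dec, _, _ = tiny_trained_decoder
        units = r.generate_population(8, rng_seed=30)
        spikes = r.simulate_spikes(flash_stim, units, rng_seed=31)
        mcfg = dec.net.config
        tcfg = r.TrainConfig.scaled_down(epochs=2, rng_seed=7)
        ds = build_dataset(spikes, flash_stim, mcfg, tcfg)
        ft, _ = decoding.finetune(dec, ds, tcfg, freeze_core=True)
        before = dec.net.core_parameters()
        after = ft.net.core_parameters()
        assert all(np.array_equal(a.data, b.data)
                   for a, b in zip(before, after))


class TestOLE:
    @staticmethod
    def _linear_dataset(noise=0.0, seed=0):
        """Targets exactly linear in binned rates (or pure noise targets)."""
        rng = np.random.default_rng(seed)
        windows = []
        w_true = rng.normal(size=5)
        for i in range(30):
            m = 10
            x = rng.poisson(3.0, size=(m, 5)).astype(float)
            y = (x @ w_true)[:, None] + noise * rng.normal(size=(m, 1))
            ids, times = [], []
            for b in range(m):
                for u in range(5):
                    ids += [u] * int(x[b, u])
                    times += list((b + rng.uniform(0, 1, int(x[b, u]))) / m)
            split = "train" if i < 20 else ("val" if i < 23 else "test")
            windows.append(ContextWindow(i, float(i), np.array(ids, dtype=int),
                                         np.array(times), (np.arange(m) + 0.5) / m,
                                         y, split))
        return decoding.DecodingDataset(windows, list(range(5)), 1, m, "flash", 1.0)

    def test_exact_linear_targets_recovered(self):
        ds = self._linear_dataset()
        assert fit_ole(ds, alpha=1e-8)["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_targets_near_zero(self):
        rng = np.random.default_rng(1)
        ds = self._linear_dataset()
        for w in ds.windows:  # replace targets with independent noise
            w.targets = rng.normal(size=w.targets.shape)
        assert abs(fit_ole(ds, alpha=0.1)["r2"]) < 0.25


def test_config_yaml_roundtrip(tmp_path):
    from retinattn.config import load_config, save_config

    cfg = r.ExperimentConfig(n_seeds=3, base_seed=11, stimulus="ball")
    path = tmp_path / "exp.yaml"
    save_config(cfg, path)
    back = load_config(path)
    assert back == cfg
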