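"""End-to-end experiment driver: multi-seed runs and artifact aggregation.

``run_experiment`` executes the full analysis on one synthetic session:

    simulate stimuli + population → light features → train one decoder per
    seed → encoder attention (entropy, divergence, importance) → ablation →
    top-K / consensus → physiological comparison → decoder attention and
    stimulus coupling → OLE baseline

and writes every artifact as CSV plus a JSON summary with full provenance
(config, seeds). Stage failures yield a partial report with per-stage
status rather than an exception.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoder_analysis as da
from . import decoding, encoder_analysis as ea, features, synthetic
from .config import ExperimentConfig

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "make_fixtures"]


def _seed_train_cfg(cfg: ExperimentConfig, seed: int):
    return dataclasses.replace(cfg.train, rng_seed=seed)


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "seeds": config.seeds,
                    "stages": {}, "per_seed": {}}
    try:
        # --- simulation -----------------------------------------------------
        flash_stim = synthetic.generate_flash(config.flash)
        if config.stimulus == "ball":
            stim = synthetic.generate_ball_trajectory(
                dataclasses.replace(config.ball, rng_seed=config.base_seed))
        else:
            stim = flash_stim
        units = synthetic.generate_population(
            config.n_units, n_informative=config.n_informative,
            rng_seed=config.base_seed)
        spikes = synthetic.simulate_spikes(stim, units, rng_seed=config.base_seed + 1)
        spikes.to_csv(out / "spikes.csv")
        stim.to_csv(out / "stimulus.csv")
        report["stages"]["simulate"] = "ok"

        # --- light features (always from a flash session of the same units) -
        flash_spikes = (spikes if config.stimulus == "flash"
                        else synthetic.simulate_spikes(flash_stim, units,
                                                       rng_seed=config.base_seed + 2))
        physiology = features.compute_population_physiology(flash_spikes, flash_stim)
        physiology.to_csv(out / "physiology.csv", index=False)
        report["stages"]["features"] = "ok"

        # --- per-seed training + encoder analysis ---------------------------
        topk_lists: list[list[int]] = []
        for seed in config.seeds:
            tcfg = _seed_train_cfg(config, seed)
            dataset = decoding.build_dataset(spikes, stim, config.model, tcfg)
            decoder, curve = decoding.train(dataset, config.model, tcfg)
            curve.to_csv(out / f"curve_seed{seed}.csv", index=False)
            test_w = dataset.split("test")
            r2 = decoder.evaluate_r2(test_w)["r2"]

            attn = ea.collect_encoder_attention(decoder, dataset.windows)
            weights = ea.spike_weights(attn)
            entropy = ea.encoder_entropy(weights)
            entropy.to_csv(out / f"encoder_entropy_seed{seed}.csv", index=False)
            div = ea.head_divergence(entropy)
            pd.DataFrame(div["D"]).to_csv(out / f"head_divergence_D_seed{seed}.csv",
                                          index=False)
            pd.DataFrame(div["p"]).to_csv(out / f"head_divergence_p_seed{seed}.csv",
                                          index=False)
            ranking = ea.unit_importance(weights)
            ranking.to_csv(out / f"importance_seed{seed}.csv", index=False)

            curves = [ea.ablation_experiment(decoder, test_w, ranking, "attention",
                                             step=config.ablation_step,
                                             rng_seed=seed),
                      ea.ablation_experiment(decoder, test_w, ranking, "random",
                                             n_random_iters=config.n_random_iters,
                                             step=config.ablation_step,
                                             rng_seed=seed)]
            ablation = pd.concat(curves, ignore_index=True)
            ablation.to_csv(out / f"ablation_seed{seed}.csv", index=False)
            attn_curve = ablation[ablation["strategy"] == "attention"]
            topk = ea.topk_at_threshold(attn_curve, config.ablation_threshold)
            order = ranking["unit_id"].to_numpy()
            topk_lists.append(order[: max(topk["k"], 0)].tolist())

            dec_attn = da.collect_decoder_attention(decoder, dataset.windows)
            dec_entropy = da.decoder_entropy(dec_attn)
            dec_entropy.to_csv(out / f"decoder_entropy_seed{seed}.csv", index=False)
            if config.stimulus == "flash":
                coupling = da.flash_coupling(dec_entropy, stim.timestamps, stim.values)
            else:
                coupling = da.directional_coupling(dec_entropy, stim.timestamps,
                                                   stim.values)
            coupling.to_csv(out / f"coupling_seed{seed}.csv", index=False)

            report["per_seed"][seed] = {
                "test_r2": r2,
                "top_k": topk,
                "mean_entropy": float(entropy["E_nats"].mean()),
                "coupling": coupling.to_dict("records"),
            }
        report["stages"]["train_and_attention"] = "ok"

        # --- consensus + physiology -----------------------------------------
        if config.n_seeds >= 2:
            cons = ea.consensus_units(topk_lists, config.consensus_fraction)
            report["consensus"] = cons["consensus"]
            if cons["consensus"]:
                phys_tests = ea.compare_physiology(cons["consensus"], physiology)
                phys_tests.to_csv(out / "physiology_tests.csv", index=False)
                report["physiology_tests"] = phys_tests.to_dict("records")
        else:
            logger.warning("n_seeds=%d < 2: consensus stage skipped", config.n_seeds)
            report["consensus"] = None
        report["stages"]["consensus"] = "ok"

        # --- linear baseline -------------------------------------------------
        tcfg = _seed_train_cfg(config, config.base_seed)
        dataset = decoding.build_dataset(spikes, stim, config.model, tcfg)
        ole = decoding.fit_ole(dataset)
        report["ole_r2"] = ole["r2"]
        report["stages"]["ole"] = "ok"
    except Exception as exc:  # partial report with stage status
        stage = next((k for k, v in report["stages"].items() if v != "ok"), "unknown")
        logger.error("experiment failed: %s", exc)
        report["stages"]["error"] = f"{type(exc).__name__}: {exc}"
        report["traceback"] = traceback.format_exc()
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def make_fixtures(profile: str = "unit") -> dict:
    """Deterministic tiny datasets for tests and examples.

    * ``toy_attention``: a (1, 4, 5) row-stochastic tensor for oracle checks.
    * ``importance_toy``: the 3-spike/2-unit w̄ example with known I(u).
    * ``flash``: a 4-unit, 3-trial flash session with planted rates.
    """
    rng = np.random.default_rng(12345)
    a = rng.random((1, 4, 5))
    a /= a.sum(axis=-1, keepdims=True)
    fixtures: dict = {
        "toy_attention": a,
        "importance_toy": {
            "wbar": np.array([[0.4, 0.4, 0.2]]),
            "unit_indices": np.array([0, 0, 1]),
            "expected": {0: 0.4, 1: 0.2},
        },
    }
    if profile in ("unit", "flash"):
        from .config import FlashStimulusConfig

        cfg = FlashStimulusConfig(on_duration=1.0, off_duration=1.0, n_trials=3)
        stim = synthetic.generate_flash(cfg)
        units = [
            synthetic.GroundTruthUnit(0, "ON", sustain=0.9, latency=0.05,
                                      baseline_rate=0.5, peak_rate=30.0),
            synthetic.GroundTruthUnit(1, "OFF", sustain=0.9, latency=0.05,
                                      baseline_rate=0.5, peak_rate=30.0),
            synthetic.GroundTruthUnit(2, "ON-OFF", on_weight=0.5, sustain=0.2,
                                      latency=0.1, baseline_rate=0.5, peak_rate=25.0),
            synthetic.GroundTruthUnit(3, "ON", sustain=0.5, latency=0.1,
                                      baseline_rate=5.0, peak_rate=5.0,
                                      informative_gain=0.0),
        ]
        fixtures["flash"] = {
            "stimulus": stim,
            "units": units,
            "spikes": synthetic.simulate_spikes(stim, units, rng_seed=777),
        }
    return fixtures
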