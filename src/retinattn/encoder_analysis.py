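"""Encoder cross-attention interpretability.

From the per-window encoder attention matrices A_{h,i} (heads x latents x
spikes) this module derives, in order:

* latent-averaged spike weights w̄ (a probability vector over the window's
  spikes) and count-normalized weights ŵ = w̄ · N_i;
* the Shannon entropy E(h, i) of w̄ in nats, one value per head per 1-s
  window — a time-resolved measure of how focused each head is;
* pairwise two-sample Kolmogorov–Smirnov divergence between head entropy
  distributions;
* the per-unit importance score I(u): the average per-spike attention a
  unit's spikes receive across heads and windows (independent of its
  firing rate);
* attention-guided ablation: removing units at inference in descending
  I(u) order versus random orders, tracking test-set R²;
* top-K / cross-seed consensus subsets and their physiological
  characterization (K-S tests and 2-D KDE summaries against the
  population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import ContextWindow, TrainedDecoder

logger = logging.getLogger(__name__)

__all__ = [
    "WindowAttention",
    "EncoderAttentionSet",
    "SpikeWeights",
    "collect_encoder_attention",
    "spike_weights",
    "encoder_entropy",
    "head_divergence",
    "unit_importance",
    "ablation_experiment",
    "topk_at_threshold",
    "consensus_units",
    "compare_physiology",
    "kde_grid",
]

PHYSIOLOGY_FEATURES = ("fbr", "sustain_index", "latency_s", "mean_rate_hz")


@dataclass
class WindowAttention:
    window_index: int
    t_end: float  # timestamp of the window end (s)
    attn: np.ndarray  # (H, L, N_i)
    unit_indices: np.ndarray  # (N_i,) roster indices per spike token
    times: np.ndarray  # (N_i,) absolute spike times


@dataclass
class EncoderAttentionSet:
    windows: list[WindowAttention]
    n_heads: int
    n_latents: int
    roster: list[int] = field(default_factory=list)


@dataclass
class SpikeWeights:
    """w̄ and ŵ per window; rows index heads, columns spikes."""

    windows: list[WindowAttention]
    wbar: list[np.ndarray]  # each (H, N_i), rows sum to 1
    what: list[np.ndarray]  # each (H, N_i), rows average to 1
    roster: list[int] = field(default_factory=list)


def collect_encoder_attention(decoder: TrainedDecoder,
                              windows: list[ContextWindow]) -> EncoderAttentionSet:
    """Run the model over windows capturing post-softmax encoder attention."""
    out = []
    for w in windows:
        decoder.predict(w, capture_attention=True)
        a = decoder.net.encoder_attention
        out.append(WindowAttention(w.index, w.start + decoder.dataset.window_len,
                                   a, w.unit_indices, w.start + w.times))
    cfg = decoder.net.config
    return EncoderAttentionSet(out, cfg.n_heads, cfg.n_latents,
                               roster=list(decoder.dataset.roster))


def spike_weights(attention: EncoderAttentionSet) -> SpikeWeights:
    """Collapse the latent dimension: w̄ = mean over latents, ŵ = w̄·N_i."""
    wbar, what = [], []
    kept = []
    for w in attention.windows:
        n = w.attn.shape[-1]
        if n == 0:
            logger.warning("window %d has no spikes; skipped", w.window_index)
            continue
        wb = w.attn.mean(axis=1)  # (H, N)
        wbar.append(wb)
        what.append(wb * n)
        kept.append(w)
    return SpikeWeights(kept, wbar, what, roster=attention.roster)


def encoder_entropy(weights: SpikeWeights) -> pd.DataFrame:
    """Shannon entropy (nats) of w̄ per head and window, stamped at window end."""
    rows = []
    for w, wb in zip(weights.windows, weights.wbar):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(wb > 0, wb * np.log(wb), 0.0)
        ent = -term.sum(axis=1)
        for h, e in enumerate(ent):
            rows.append({"t_s": w.t_end, "head": h, "E_nats": float(e),
                         "n_spikes": wb.shape[1]})
    return pd.DataFrame(rows)


def head_divergence(entropy: pd.DataFrame) -> dict:
    """Pairwise two-sample K-S tests between head entropy distributions.

    Returns symmetric D and raw-p matrices (diagonal NaN) plus a
    Bonferroni-adjusted p matrix over the H·(H−1)/2 comparisons.
    """
    heads = sorted(entropy["head"].unique())
    n = len(heads)
    samples = [entropy.loc[entropy["head"] == h, "E_nats"].to_numpy() for h in heads]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 windows per head for K-S tests")
    d = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            res = stats.ks_2samp(samples[i], samples[j])
            d[i, j] = d[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    n_tests = n * (n - 1) // 2
    return {"heads": heads, "D": d, "p": p,
            "p_bonferroni": np.clip(p * n_tests, 0.0, 1.0)}


def unit_importance(weights: SpikeWeights) -> pd.DataFrame:
    """Importance I(u): mean per-spike attention across heads and windows.

    For each head and each window where unit u fires, its spikes' w̄ values
    are averaged; I(u) is the mean of these per-(head, window) averages.
    Units with no spikes anywhere get NaN and are ranked last.
    """
    n_units = len(weights.roster)
    total = np.zeros(n_units)
    count = np.zeros(n_units)
    for w, wb in zip(weights.windows, weights.wbar):
        h = wb.shape[0]
        for u in np.unique(w.unit_indices):
            mask = w.unit_indices == u
            total[u] += wb[:, mask].mean(axis=1).sum()  # sum over heads of per-spike mean
            count[u] += h
    with np.errstate(invalid="ignore"):
        importance = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    silent = np.flatnonzero(count == 0)
    if len(silent):
        logger.info("%d units had no spikes; importance undefined", len(silent))
    df = pd.DataFrame({"unit_index": np.arange(n_units),
                       "unit_id": weights.roster,
                       "importance": importance,
                       "n_spike_windows": (count / max(wb.shape[0], 1)).astype(int)})
    # descending importance, NaN last, ties broken by unit_id
    df["_key"] = np.where(np.isnan(df["importance"]), -np.inf, df["importance"])
    df = df.sort_values(["_key", "unit_id"], ascending=[False, True],
                        kind="stable").drop(columns="_key").reset_index(drop=True)
    df["rank"] = np.arange(1, n_units + 1)
    return df


def ablation_experiment(decoder: TrainedDecoder, test_windows: list[ContextWindow],
                        ranking: pd.DataFrame, strategy: str = "attention",
                        n_random_iters: int = 20, step: int = 1,
                        rng_seed: int = 0) -> pd.DataFrame:
    """Sequential unit removal at inference, tracking test R².

    ``attention``: remove in descending I(u) order (one curve).
    ``random``: ``n_random_iters`` independent random orders.
    No retraining — spike tokens of removed units are dropped from the input.
    Returns a tidy frame (strategy, iter, step, n_removed, r2); step 0 is the
    unablated test R².
    """
    order_attn = ranking["unit_index"].to_numpy()
    n_units = len(order_attn)
    rng = np.random.default_rng(rng_seed)
    if strategy == "attention":
        orders = [order_attn]
    elif strategy == "random":
        orders = [rng.permutation(n_units) for _ in range(n_random_iters)]
    else:
        raise ValueError("strategy must be 'attention' or 'random'")
    steps = list(range(0, n_units + 1, step))
    if steps[-1] != n_units:
        steps.append(n_units)
    rows = []
    for it, order in enumerate(orders):
        for s_idx, n_removed in enumerate(steps):
            excluded = set(order[:n_removed].tolist())
            r2 = decoder.evaluate_r2(test_windows, exclude_units=excluded)["r2"]
            rows.append({"strategy": strategy, "iter": it, "step": s_idx,
                         "n_removed": n_removed, "r2": r2})
    return pd.DataFrame(rows)


def topk_at_threshold(curve: pd.DataFrame, threshold: float = 0.5) -> dict:
    """Smallest number of removed units at which R² first drops to ≤ threshold.

    Returns ``{"k": int, "crossed": bool}``; if the curve never crosses the
    threshold, k equals the total unit count and ``crossed`` is False. A
    curve that starts at or below threshold yields k = 0 (model failed
    before any ablation).
    """
    c = curve.sort_values("n_removed")
    below = c.loc[c["r2"] <= threshold, "n_removed"]
    if below.empty:
        logger.warning("ablation curve never crossed R²=%.2f", threshold)
        return {"k": int(c["n_removed"].max()), "crossed": False}
    k = int(below.iloc[0])
    if k == 0:
        logger.warning("unablated R² already at/below threshold")
    return {"k": k, "crossed": True}


def consensus_units(topk_lists: list[list[int]], min_fraction: float = 0.5) -> dict:
    """Units present in at least ``min_fraction`` of the per-seed top-K lists."""
    if len(topk_lists) < 2:
        raise ValueError("consensus requires at least 2 seeds")
    counts: dict[int, int] = {}
    for lst in topk_lists:
        for u in set(lst):
            counts[u] = counts.get(u, 0) + 1
    need = int(np.ceil(min_fraction * len(topk_lists)))
    consensus = sorted(u for u, c in counts.items() if c >= need)
    if not consensus:
        logger.warning("empty consensus set across %d seeds", len(topk_lists))
    return {"consensus": consensus, "counts": counts, "min_count": need}


def compare_physiology(subset_ids: list[int], physiology: pd.DataFrame,
                       other_ids: list[int] | None = None,
                       features: tuple[str, ...] = PHYSIOLOGY_FEATURES,
                       label: str = "subset_vs_population") -> pd.DataFrame:
    """Two-sample K-S tests on light-response features.

    Compares the subset against the full population (default) or against a
    second subset. Returns rows (comparison, feature, D, p, n_subset, n_other).
    """
    sub = physiology[physiology["unit_id"].isin(subset_ids)]
    other = (physiology if other_ids is None
             else physiology[physiology["unit_id"].isin(other_ids)])
    if sub.empty or other.empty:
        raise ValueError("both comparison groups must be nonempty")
    if len(sub) < 5:
        logger.warning("subset has fewer than 5 units; K-S power is low")
    rows = []
    for feat in features:
        a = sub[feat].dropna().to_numpy()
        b = other[feat].dropna().to_numpy()
        res = stats.ks_2samp(a, b)
        rows.append({"comparison": label, "feature": feat,
                     "D": float(res.statistic), "p": float(res.pvalue),
                     "n_subset": len(a), "n_other": len(b)})
    return pd.DataFrame(rows)


def kde_grid(physiology: pd.DataFrame, x_feature: str, y_feature: str,
             unit_ids: list[int] | None = None, n_grid: int = 50) -> dict:
    """2-D Gaussian KDE of two features on a regular grid (for joint plots)."""
    df = physiology if unit_ids is None else physiology[physiology["unit_id"].isin(unit_ids)]
    x = df[x_feature].dropna().to_numpy()
    y = df.loc[df[x_feature].notna(), y_feature].to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    kde = stats.gaussian_kde(np.vstack([x[ok], y[ok]]))
    gx = np.linspace(x[ok].min(), x[ok].max(), n_grid)
    gy = np.linspace(y[ok].min(), y[ok].max(), n_grid)
    mx, my = np.meshgrid(gx, gy)
    density = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(n_grid, n_grid)
    return {"x": gx, "y": gy, "density": density}
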