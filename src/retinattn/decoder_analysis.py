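"""Decoder cross-attention analysis: latent retrieval and stimulus coupling.

The decoder attends from output timestamps to the L latent tokens; its
attention matrices D_h (heads x outputs x latents) yield an entropy trace
at the reconstructed-stimulus sampling rate. Coupling to the stimulus is
quantified per head:

* flash — Pearson r between the entropy trace and the light intensity;
* ball — the trajectory is decomposed into rectified per-frame displacement
  components (+X, −X, +Y, −Y) and each head gets two 2-D correlation
  vectors, one for positive and one for negative displacements.

"Displacement" means the per-frame position difference (a velocity
component); correlating against rectified absolute position instead is
available via ``mode="position"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import ContextWindow, TrainedDecoder

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderAttentionSet",
    "collect_decoder_attention",
    "decoder_entropy",
    "flash_coupling",
    "directional_decompose",
    "directional_coupling",
]


@dataclass
class DecoderAttentionSet:
    """Per-head decoder attention stacked over windows.

    ``attn`` has shape (heads, M_total, latents); ``out_times`` are the
    absolute timestamps of the M_total output tokens.
    """

    attn: np.ndarray
    out_times: np.ndarray
    n_heads: int
    n_latents: int


def collect_decoder_attention(decoder: TrainedDecoder,
                              windows: list[ContextWindow]) -> DecoderAttentionSet:
    blocks, times = [], []
    for w in windows:
        decoder.predict(w, capture_attention=True)
        blocks.append(decoder.net.decoder_attention)
        times.append(w.start + w.out_times)
    attn = np.concatenate(blocks, axis=1)
    cfg = decoder.net.config
    return DecoderAttentionSet(attn, np.concatenate(times), cfg.n_heads,
                               cfg.n_latents)


def decoder_entropy(attention: DecoderAttentionSet) -> pd.DataFrame:
    """Shannon entropy (nats) of each output token's latent distribution."""
    d = attention.attn
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d), 0.0)
    ent = -term.sum(axis=-1)  # (H, M)
    rows = []
    for h in range(attention.n_heads):
        for m, t in enumerate(attention.out_times):
            rows.append({"t_s": float(t), "head": h, "E_nats": float(ent[h, m])})
    return pd.DataFrame(rows)


def _align(entropy_head: pd.DataFrame, trace_t: np.ndarray,
           trace_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample a stimulus-side series onto the entropy timestamps."""
    t = entropy_head["t_s"].to_numpy()
    return entropy_head["E_nats"].to_numpy(), np.interp(t, trace_t, trace_v)


def flash_coupling(entropy: pd.DataFrame, intensity_t: np.ndarray,
                   intensity_v: np.ndarray) -> pd.DataFrame:
    """Pearson r between each head's entropy trace and the light intensity."""
    rows = []
    for h in sorted(entropy["head"].unique()):
        e, s = _align(entropy[entropy["head"] == h], intensity_t, intensity_v)
        if np.ptp(e) == 0 or np.ptp(s) == 0:
            logger.warning("zero-variance trace for head %d; r undefined", h)
            rows.append({"head": h, "component": "flash", "r": np.nan})
            continue
        rows.append({"head": h, "component": "flash",
                     "r": float(stats.pearsonr(e, s).statistic)})
    return pd.DataFrame(rows)


def directional_decompose(positions: np.ndarray, mode: str = "displacement") -> dict:
    """Rectified Cartesian components of a 2-D trajectory.

    ``displacement`` (default): per-frame position differences split into
    positive and negative parts per axis, so (+X) − (−X) reconstructs Δx
    exactly. ``position``: rectified position relative to the field center.
    Returned arrays have length len(positions) − 1 (displacement) or
    len(positions) (position).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("expected an (n, 2) trajectory")
    if len(positions) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    if mode == "displacement":
        d = np.diff(positions, axis=0)
    elif mode == "position":
        d = positions - positions.mean(axis=0)
    else:
        raise ValueError("mode must be 'displacement' or 'position'")
    return {"+X": np.maximum(d[:, 0], 0.0), "-X": np.maximum(-d[:, 0], 0.0),
            "+Y": np.maximum(d[:, 1], 0.0), "-Y": np.maximum(-d[:, 1], 0.0)}


def directional_coupling(entropy: pd.DataFrame, trajectory_t: np.ndarray,
                         positions: np.ndarray,
                         mode: str = "displacement") -> pd.DataFrame:
    """Per-head correlation vectors against the four rectified components.

    Rows carry (head, component, r); the positive-direction vector of a head
    is (r_{+X}, r_{+Y}) and the negative-direction vector (r_{−X}, r_{−Y}).
    """
    comps = directional_decompose(positions, mode)
    if mode == "displacement":
        t = 0.5 * (trajectory_t[1:] + trajectory_t[:-1])
    else:
        t = trajectory_t
    rows = []
    for h in sorted(entropy["head"].unique()):
        sub = entropy[entropy["head"] == h]
        for name, series in comps.items():
            e, s = _align(sub, t, series)
            if np.ptp(s) == 0 or np.ptp(e) == 0:
                logger.warning("constant %s component; r undefined for head %d",
                               name, h)
                rows.append({"head": h, "component": name, "r": np.nan})
                continue
            rows.append({"head": h, "component": name,
                         "r": float(stats.pearsonr(e, s).statistic)})
    return pd.DataFrame(rows)
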