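"""Spike-token latent-attention encoder–decoder (perceiver-style).

Architecture, following the POYO family of population decoders:

1. every spike becomes one token: a learnable unit-identity embedding plus a
   sinusoidal encoding of its continuous time within the 1-s context window;
2. one cross-attention block compresses the N_i spike tokens of a window
   into L learned latent tokens (this is the attention the unit-level
   interpretability stack reads out);
3. a stack of self-attention blocks refines the latents;
4. one cross-attention block queries the latents from output tokens placed
   on the output time grid (time encoding + session embedding);
5. an MLP head maps output tokens to stimulus features (1-D intensity for
   the flash, 2-D ball position).

The encoder cross-attention matrices A_{h,i} (heads x latents x spikes) and
decoder matrices D_h (heads x outputs x latents) are captured post-softmax,
pre-dropout, on demand.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .nn import (
    AttentionBlock,
    Linear,
    MLP,
    Module,
    Parameter,
    Tensor,
    embedding,
    sinusoidal_time_encoding,
)

__all__ = ["SpikeDecoderNet"]


class SpikeDecoderNet(Module):
    def __init__(self, config: ModelConfig, n_units: int, out_dim: int,
                 n_sessions: int = 1, rng_seed: int = 0):
        self.config = config
        self.n_units = n_units
        self.out_dim = out_dim
        self.n_sessions = n_sessions
        rng = np.random.default_rng(rng_seed)
        d = config.latent_dim
        scale = 1.0 / np.sqrt(d)
        self.unit_emb = Parameter(rng.normal(0, scale, size=(n_units, d)))
        self.session_emb = Parameter(rng.normal(0, scale, size=(n_sessions, d)))
        self.latents = Parameter(rng.normal(0, scale, size=(config.n_latents, d)))
        self.enc_cross = AttentionBlock(d, config.n_heads, config.head_dim, rng,
                                        config.dropout)
        self.self_blocks = [
            AttentionBlock(d, config.n_heads, config.head_dim, rng, config.dropout)
            for _ in range(config.depth)
        ]
        self.dec_cross = AttentionBlock(d, config.n_heads, config.head_dim, rng,
                                        config.dropout)
        self.query_proj = Linear(d, d, rng)
        self.head = MLP(d, 2 * d, out_dim, rng, config.dropout)
        # dropout noise stream, reseedable for reproducible training
        self._drop_rng = np.random.default_rng(rng.integers(2**31))

    def reseed_dropout(self, seed: int) -> None:
        self._drop_rng = np.random.default_rng(seed)

    # -- forward ------------------------------------------------------------

    def forward(self, unit_ids: np.ndarray, times: np.ndarray,
                out_times: np.ndarray, session_index: int = 0,
                training: bool = False, capture_attention: bool = False):
        """Decode one context window.

        Parameters
        ----------
        unit_ids, times:
            spike tokens — roster indices and times (s) within the window.
        out_times:
            output grid times (s) within the window.
        Returns
        -------
        predictions : Tensor of shape (len(out_times), out_dim)
        """
        unit_ids = np.asarray(unit_ids, dtype=int)
        if len(unit_ids) == 0:
            raise ValueError("empty window: no spike tokens")
        if unit_ids.max() >= self.n_units:
            raise ValueError("unit id outside the embedding roster")
        d = self.config.latent_dim
        rng = self._drop_rng
        tok = embedding(self.unit_emb, unit_ids) + Tensor(
            sinusoidal_time_encoding(times, d))
        lat = self.enc_cross(self.latents, tok, rng, training,
                             capture=capture_attention)
        for block in self.self_blocks:
            lat = block(lat, None, rng, training)
        q = self.query_proj(Tensor(sinusoidal_time_encoding(out_times, d)))
        q = q + embedding(self.session_emb,
                          np.full(len(out_times), session_index, dtype=int))
        out = self.dec_cross(q, lat, rng, training, capture=capture_attention)
        return self.head(out, rng, training)

    # -- attention access ---------------------------------------------------

    @property
    def encoder_attention(self) -> np.ndarray:
        """A_{h,i} of the last captured forward pass: (heads, latents, spikes)."""
        a = self.enc_cross.attn.last_attn
        if a is None:
            raise RuntimeError("no captured encoder attention; forward with capture_attention=True")
        return a

    @property
    def decoder_attention(self) -> np.ndarray:
        """D_h of the last captured forward pass: (heads, outputs, latents)."""
        a = self.dec_cross.attn.last_attn
        if a is None:
            raise RuntimeError("no captured decoder attention; forward with capture_attention=True")
        return a

    # -- transfer -----------------------------------------------------------

    def spawn_for_new_session(self, n_units: int, rng_seed: int = 0,
                              n_sessions: int = 1) -> "SpikeDecoderNet":
        """Copy of the trained core with fresh unit/session embeddings.

        Used for fine-tuning on an unseen retina: attention blocks, latents
        and head are copied; unit and session embeddings are re-initialized
        for the new roster.
        """
        new = SpikeDecoderNet(self.config, n_units, self.out_dim, n_sessions, rng_seed)
        keep = {id(new.unit_emb), id(new.session_emb)}
        src = [p for p in self.parameters()
               if id(p) not in (id(self.unit_emb), id(self.session_emb))]
        dst = [p for p in new.parameters() if id(p) not in keep]
        for s, t in zip(src, dst):
            t.data = s.data.copy()
        return new

    def core_parameters(self) -> list[Parameter]:
        """All parameters except the per-session embedding tables."""
        skip = {id(self.unit_emb), id(self.session_emb)}
        return [p for p in self.parameters() if id(p) not in skip]

    def embedding_parameters(self) -> list[Parameter]:
        return [self.unit_emb, self.session_emb]
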