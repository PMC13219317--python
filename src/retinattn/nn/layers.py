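"""Attention layers and optimizer built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, dropout, layer_norm, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MLP",
    "MultiheadAttention",
    "AttentionBlock",
    "AdamW",
    "sinusoidal_time_encoding",
]


class Module:
    """Base class: recursively collects Parameters from attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MLP(Module):
    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator,
                 p_dropout: float = 0.0):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)
        self.p_dropout = p_dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        h = self.fc1(x).gelu()
        if training and rng is not None:
            h = dropout(h, self.p_dropout, rng, training)
        return self.fc2(h)


class MultiheadAttention(Module):
    """Multi-head scaled dot-product attention (cross or self).

    The post-softmax, pre-dropout weights of the most recent forward pass
    are stored in ``last_attn`` with shape (heads, n_queries, n_keys) when
    ``capture=True`` — these are the matrices the interpretability stack
    consumes.
    """

    def __init__(self, d_model: int, n_heads: int, head_dim: int,
                 rng: np.random.Generator, p_dropout: float = 0.0):
        self.n_heads = n_heads
        self.head_dim = head_dim
        inner = n_heads * head_dim
        self.wq = Linear(d_model, inner, rng)
        self.wk = Linear(d_model, inner, rng)
        self.wv = Linear(d_model, inner, rng)
        self.wo = Linear(inner, d_model, rng)
        self.p_dropout = p_dropout
        self.last_attn: np.ndarray | None = None

    def __call__(self, query: Tensor, keyval: Tensor,
                 rng: np.random.Generator | None = None, training: bool = False,
                 capture: bool = False) -> Tensor:
        m = query.shape[0]
        n = keyval.shape[0]
        h, dh = self.n_heads, self.head_dim
        q = self.wq(query).reshape(m, h, dh).swapaxes(0, 1)   # (H, M, dh)
        k = self.wk(keyval).reshape(n, h, dh).swapaxes(0, 1)  # (H, N, dh)
        v = self.wv(keyval).reshape(n, h, dh).swapaxes(0, 1)
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(dh))  # (H, M, N)
        attn = softmax(scores, axis=-1)
        if capture:
            self.last_attn = attn.data.copy()
        if training and rng is not None:
            attn = dropout(attn, self.p_dropout, rng, training)
        out = (attn @ v).swapaxes(0, 1).reshape(m, h * dh)
        return self.wo(out)


class AttentionBlock(Module):
    """Pre-norm residual block: attention followed by a feed-forward MLP."""

    def __init__(self, d_model: int, n_heads: int, head_dim: int,
                 rng: np.random.Generator, p_dropout: float = 0.0,
                 mlp_ratio: int = 2):
        self.ln_q = LayerNorm(d_model)
        self.ln_kv = LayerNorm(d_model)
        self.attn = MultiheadAttention(d_model, n_heads, head_dim, rng, p_dropout)
        self.ln_mlp = LayerNorm(d_model)
        self.mlp = MLP(d_model, mlp_ratio * d_model, d_model, rng, p_dropout)

    def __call__(self, x: Tensor, context: Tensor | None = None,
                 rng: np.random.Generator | None = None, training: bool = False,
                 capture: bool = False) -> Tensor:
        kv = x if context is None else context
        x = x + self.attn(self.ln_q(x), self.ln_kv(kv), rng, training, capture)
        x = x + self.mlp(self.ln_mlp(x), rng, training)
        return x


class AdamW(Module):
    """AdamW with decoupled weight decay (decay on matrices only)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if self.weight_decay and p.data.ndim >= 2:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sinusoidal_time_encoding(times: np.ndarray, dim: int,
                             min_period: float = 0.002,
                             max_period: float = 2.0) -> np.ndarray:
    """Continuous-time sinusoidal features for spike/output timestamps.

    Periods are log-spaced between ``min_period`` and ``max_period`` seconds
    so sub-millisecond spike timing within a 1-s context window is resolvable.
    """
    times = np.asarray(times, dtype=np.float64)
    half = dim // 2
    periods = np.geomspace(min_period, max_period, half)
    phase = 2.0 * np.pi * times[:, None] / periods[None, :]
    enc = np.zeros((len(times), dim))
    enc[:, 0:2 * half:2] = np.sin(phase)
    enc[:, 1:2 * half:2] = np.cos(phase)
    return enc
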