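"""Dataset construction, training and evaluation of the spike decoder.

The continuous recording is tiled with non-overlapping 1-s context windows.
Train/validation/test splits are assigned to longer temporal blocks *before*
windowing, so no window ever spans a split boundary and there is no leakage
between splits. Targets are read off the stimulus trace on a per-window
output grid and z-scored with train-split statistics for optimization; all
reported R² values are computed on the original stimulus scale.

Also provides the optimal linear estimator (OLE) baseline: ridge regression
from binned firing rates to stimulus features on the same splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .config import ModelConfig, TrainConfig
from .model import SpikeDecoderNet
from .nn import AdamW, Tensor
from .synthetic import SpikeEventTable, StimulusTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ContextWindow",
    "DecodingDataset",
    "TrainedDecoder",
    "tokenize",
    "build_dataset",
    "train",
    "finetune",
    "r2_score_columns",
    "fit_ole",
]


@dataclass
class ContextWindow:
    """Spike tokens and targets of one context window."""

    index: int
    start: float
    unit_indices: np.ndarray  # roster indices, one per spike token
    times: np.ndarray  # spike times within the window (s)
    out_times: np.ndarray  # output grid within the window (s)
    targets: np.ndarray  # (M, out_dim), original stimulus scale
    split: str = "train"

    @property
    def n_tokens(self) -> int:
        return len(self.times)


@dataclass
class DecodingDataset:
    windows: list[ContextWindow]
    roster: list[int]
    out_dim: int
    output_rate: float
    stimulus_kind: str
    window_len: float
    meta: dict = field(default_factory=dict)

    def split(self, name: str) -> list[ContextWindow]:
        return [w for w in self.windows if w.split == name]


def tokenize(spikes: SpikeEventTable, start: float, window_len: float,
             unit_index: dict[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """One token per spike in [start, start + window_len).

    Returns roster indices and within-window times; tokens are ordered by
    time, though the encoder is permutation-invariant to this order.
    """
    df = spikes.df
    mask = (df["time_s"].to_numpy() >= start) & (df["time_s"].to_numpy() < start + window_len)
    sub = df.loc[mask].sort_values("time_s", kind="stable")
    unknown = set(sub["unit_id"]) - set(unit_index)
    if unknown:
        raise KeyError(f"unit ids without embedding: {sorted(unknown)[:5]}")
    idx = np.array([unit_index[u] for u in sub["unit_id"]], dtype=int)
    return idx, sub["time_s"].to_numpy() - start


def _assign_blocks(duration: float, block_len: float, split: tuple[float, float, float],
                   rng: np.random.Generator) -> list[tuple[float, str]]:
    """Shuffle temporal blocks and assign them to splits by cumulative fraction."""
    n_blocks = int(duration // block_len)
    if n_blocks < 3:
        raise ValueError("recording too short for a 3-way block split")
    order = rng.permutation(n_blocks)
    n_train = max(1, int(round(split[0] * n_blocks)))
    n_val = max(1, int(round(split[1] * n_blocks)))
    n_val = min(n_val, n_blocks - n_train - 1)
    labels = {}
    for rank, b in enumerate(order):
        if rank < n_train:
            labels[b] = "train"
        elif rank < n_train + n_val:
            labels[b] = "val"
        else:
            labels[b] = "test"
    return [(b * block_len, labels[b]) for b in range(n_blocks)]


def build_dataset(spikes: SpikeEventTable, stimulus: StimulusTrace,
                  model_cfg: ModelConfig, train_cfg: TrainConfig) -> DecodingDataset:
    """Window the recording, attach targets, and label block-wise splits."""
    if stimulus.kind == "flash":
        default_block = stimulus.meta["config"].period
        out_dim = 1
    else:
        default_block = 4.0
        out_dim = 2
    block_len = train_cfg.block_len or default_block
    win = model_cfg.context_window
    m = int(round(win * model_cfg.output_rate))
    rng = np.random.default_rng(train_cfg.rng_seed)
    blocks = _assign_blocks(spikes.duration, block_len, train_cfg.split, rng)
    unit_index = {u: i for i, u in enumerate(spikes.roster)}
    windows: list[ContextWindow] = []
    idx = 0
    for block_start, label in blocks:
        n_win = int(block_len // win)
        for k in range(n_win):
            start = block_start + k * win
            if start + win > spikes.duration + 1e-9:
                break
            ids, times = tokenize(spikes, start, win, unit_index)
            if len(ids) == 0:
                logger.warning("skipping empty window at t=%.1f s", start)
                continue
            out_rel = (np.arange(m) + 0.5) / model_cfg.output_rate
            targets = np.atleast_2d(stimulus.value_at(start + out_rel))
            if targets.shape[0] == 1 and m > 1:
                targets = targets.T
            windows.append(ContextWindow(idx, start, ids, times, out_rel,
                                         targets.reshape(m, out_dim), label))
            idx += 1
    return DecodingDataset(windows, list(spikes.roster), out_dim,
                           model_cfg.output_rate, stimulus.kind, win,
                           meta={"block_len": block_len, "seed": train_cfg.rng_seed})


def r2_score_columns(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """R² per output dimension; NaN where the target has zero variance."""
    y_true = np.atleast_2d(y_true)
    y_pred = np.atleast_2d(y_pred)
    ss_res = ((y_true - y_pred) ** 2).sum(axis=0)
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = np.where(ss_tot == 0, np.nan, r2)
    if np.isnan(r2).any():
        logger.warning("zero-variance target dimension: R² undefined")
    return r2


class TrainedDecoder:
    """A trained network plus the target scaling and roster it was fit with."""

    def __init__(self, net: SpikeDecoderNet, dataset: DecodingDataset,
                 train_cfg: TrainConfig, target_mean: np.ndarray,
                 target_std: np.ndarray, session_index: int = 0):
        self.net = net
        self.dataset = dataset
        self.train_cfg = train_cfg
        self.target_mean = target_mean
        self.target_std = target_std
        self.session_index = session_index
        # stimulus features are physically bounded (screen size, luminance
        # range); the readout is constrained to the range seen in training
        train_targets = np.concatenate([w.targets for w in dataset.split("train")])
        self.target_lo = train_targets.min(axis=0)
        self.target_hi = train_targets.max(axis=0)

    def predict(self, window: ContextWindow,
                exclude_units: set[int] | frozenset[int] | None = None,
                capture_attention: bool = False) -> np.ndarray:
        """Decode one window (original stimulus scale).

        ``exclude_units`` drops all spike tokens of the given roster indices
        at inference (the ablation primitive). A window left with no tokens
        predicts the training-set mean (chance level).
        """
        ids, times = window.unit_indices, window.times
        if exclude_units:
            keep = ~np.isin(ids, list(exclude_units))
            ids, times = ids[keep], times[keep]
        if len(ids) == 0:
            return np.tile(self.target_mean, (len(window.out_times), 1))
        out = self.net.forward(ids, times, window.out_times, self.session_index,
                               training=False, capture_attention=capture_attention)
        pred = out.data * self.target_std + self.target_mean
        return np.clip(pred, self.target_lo, self.target_hi)

    def evaluate_r2(self, windows: list[ContextWindow],
                    exclude_units: set[int] | None = None) -> dict:
        """R² on concatenated windows, per dimension and averaged."""
        if not windows:
            raise ValueError("no windows to evaluate")
        preds = np.concatenate([self.predict(w, exclude_units) for w in windows])
        truth = np.concatenate([w.targets for w in windows])
        per_dim = r2_score_columns(truth, preds)
        return {"r2": float(np.mean(per_dim)), "r2_per_dim": per_dim}


def _scaled_targets(w: ContextWindow, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (w.targets - mean) / std


def _lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Base lr, decaying geometrically to factor*lr over the final fraction."""
    start = int(np.ceil((1.0 - cfg.lr_decay_frac) * cfg.epochs))
    if epoch < start or cfg.epochs == start:
        return cfg.lr
    frac = (epoch - start + 1) / (cfg.epochs - start)
    return cfg.lr * cfg.lr_decay_factor**frac


def _run_training(net: SpikeDecoderNet, dataset: DecodingDataset,
                  train_cfg: TrainConfig, params, session_index: int = 0):
    train_w = dataset.split("train")
    val_w = dataset.split("val")
    if not train_w:
        raise ValueError("empty training split")
    mean = np.concatenate([w.targets for w in train_w]).mean(axis=0)
    std = np.concatenate([w.targets for w in train_w]).std(axis=0)
    std = np.where(std == 0, 1.0, std)
    decoder = TrainedDecoder(net, dataset, train_cfg, mean, std, session_index)
    opt = AdamW(params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.rng_seed)
    net.reseed_dropout(int(rng.integers(2**31)))
    best = (np.inf, None)
    curve = []
    for epoch in range(train_cfg.epochs):
        opt.lr = _lr_at(epoch, train_cfg)
        order = rng.permutation(len(train_w))
        losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            batch = [train_w[i] for i in order[lo:lo + train_cfg.batch_size]]
            opt.zero_grad()
            batch_loss = 0.0
            for w in batch:
                ids, times = w.unit_indices, w.times
                if train_cfg.unit_dropout > 0:
                    # hide whole units per window: robustness to unit loss,
                    # and reliance spread across redundant units
                    hide = rng.random(net.n_units) < train_cfg.unit_dropout
                    keep = ~hide[ids]
                    if keep.any():
                        ids, times = ids[keep], times[keep]
                out = net.forward(ids, times, w.out_times,
                                  session_index, training=True)
                target = Tensor(_scaled_targets(w, mean, std))
                loss = ((out - target) ** 2).mean() * (1.0 / len(batch))
                loss.backward()
                batch_loss += loss.item() * len(batch)
            losses.append(batch_loss / len(batch))
            if not np.isfinite(losses[-1]):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={opt.lr:.2e}); aborting")
            opt.step()
        val_loss, val_r2 = np.nan, np.nan
        if val_w:
            preds = np.concatenate([decoder.predict(w) for w in val_w])
            truth = np.concatenate([w.targets for w in val_w])
            val_loss = float((((preds - truth) / std) ** 2).mean())
            val_r2 = float(np.mean(r2_score_columns(truth, preds)))
            if val_loss < best[0]:
                best = (val_loss, [p.data.copy() for p in net.parameters()])
        curve.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                      "val_loss": val_loss, "val_r2": val_r2})
    if best[1] is not None:
        net.load_state_arrays(best[1])
    return decoder, pd.DataFrame(curve)


def train(dataset: DecodingDataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
          session_index: int = 0, n_sessions: int = 1):
    """Train a decoder from scratch; returns (TrainedDecoder, learning curve)."""
    net = SpikeDecoderNet(model_cfg, n_units=len(dataset.roster),
                          out_dim=dataset.out_dim, n_sessions=n_sessions,
                          rng_seed=train_cfg.rng_seed)
    return _run_training(net, dataset, train_cfg, net.parameters(), session_index)


def finetune(pretrained: TrainedDecoder, dataset: DecodingDataset,
             train_cfg: TrainConfig, freeze_core: bool = False):
    """Adapt a pretrained core to a new session with fresh embeddings.

    The attention core and head are copied from ``pretrained``; unit and
    session embeddings are re-initialized for the new roster. With
    ``freeze_core`` only the embeddings are optimized.
    """
    net = pretrained.net.spawn_for_new_session(
        n_units=len(dataset.roster), rng_seed=train_cfg.rng_seed)
    params = net.embedding_parameters() if freeze_core else net.parameters()
    return _run_training(net, dataset, train_cfg, params)


# ---------------------------------------------------------------------------
# OLE baseline
# ---------------------------------------------------------------------------


def _binned_rates(dataset: DecodingDataset, windows: list[ContextWindow]) -> np.ndarray:
    """Per-unit spike counts in output-grid bins, stacked across windows."""
    n_units = len(dataset.roster)
    bin_len = 1.0 / dataset.output_rate
    rows = []
    for w in windows:
        m = len(w.out_times)
        x = np.zeros((m, n_units))
        bins = np.minimum((w.times / bin_len).astype(int), m - 1)
        np.add.at(x, (bins, w.unit_indices), 1.0)
        rows.append(x)
    return np.concatenate(rows)


def fit_ole(dataset: DecodingDataset, alpha: float = 0.1) -> dict:
    """Ridge-regression optimal linear estimator on binned rates.

    Fits on the train split and reports R² on the test split, using the
    same temporal-block partition and output grid as the transformer.
    """
    train_w = dataset.split("train")
    test_w = dataset.split("test")
    x_train = _binned_rates(dataset, train_w)
    y_train = np.concatenate([w.targets for w in train_w])
    x_test = _binned_rates(dataset, test_w)
    y_test = np.concatenate([w.targets for w in test_w])
    model = Ridge(alpha=alpha)
    model.fit(x_train, y_train)
    pred = np.atleast_2d(model.predict(x_test))
    if pred.shape[0] == 1:
        pred = pred.T
    per_dim = r2_score_columns(y_test, pred.reshape(y_test.shape))
    return {"r2": float(np.mean(per_dim)), "r2_per_dim": per_dim, "model": model}
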