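"""Configuration objects for stimuli, model, training and experiments.

All configs are plain dataclasses that round-trip through YAML/JSON so a
whole experiment is reproducible from one file plus its seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "FlashStimulusConfig",
    "BallStimulusConfig",
    "ModelConfig",
    "TrainConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


@dataclass
class FlashStimulusConfig:
    """Full-field flash protocol: ON phase then OFF phase, repeated."""

    on_duration: float = 3.0
    off_duration: float = 3.0
    n_trials: int = 10
    frame_rate: float = 60.0
    on_intensity: float = 1.0
    off_intensity: float = 0.0

    def __post_init__(self):
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("flash phase durations must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def period(self) -> float:
        return self.on_duration + self.off_duration

    @property
    def total_duration(self) -> float:
        return self.n_trials * self.period


@dataclass
class BallStimulusConfig:
    """Moving ball on a dark field following a fractional Brownian trajectory.

    One trajectory of ``duration`` seconds is generated and presented for
    ``n_trials`` identical repeats. The raw fBm increments are rescaled so the
    realized mean speed matches ``target_mean_speed`` (px/s); the trajectory
    is reflected at the field borders so the ball never leaves the screen.
    """

    hurst: float = 0.9
    duration: float = 20.0
    n_trials: int = 10
    frame_rate: float = 60.0
    field_size: tuple[float, float] = (400.0, 400.0)
    target_mean_speed: float = 232.0
    ball_size: tuple[float, float] = (28.0, 36.6)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("Hurst exponent must lie in (0, 1)")
        if self.duration <= 0 or self.n_trials < 1 or self.frame_rate <= 0:
            raise ValueError("invalid ball stimulus timing")
        self.field_size = tuple(self.field_size)
        self.ball_size = tuple(self.ball_size)

    @property
    def total_duration(self) -> float:
        return self.n_trials * self.duration


@dataclass
class ModelConfig:
    """Spike-token latent-attention architecture hyperparameters.

    Defaults follow the full-scale profile (latent dimension 128, 64 latents,
    six self-attention layers, eight heads of dimension 64, dropout 0.3,
    1-s context windows). ``scaled_down()`` returns the desk-scale profile
    used by the test-suite experiments.
    """

    latent_dim: int = 128
    n_latents: int = 64
    depth: int = 6
    n_heads: int = 8
    head_dim: int = 64
    dropout: float = 0.3
    context_window: float = 1.0
    output_rate: float = 30.0  # output tokens per second within a window

    def __post_init__(self):
        for name in ("latent_dim", "n_latents", "depth", "n_heads", "head_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def scaled_down(cls, **overrides) -> "ModelConfig":
        base = dict(latent_dim=64, n_latents=32, depth=2, n_heads=4,
                    head_dim=16, dropout=0.1, output_rate=20.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainConfig:
    """Optimization settings: AdamW on MSE with a late learning-rate decay.

    The recording is partitioned into non-overlapping temporal blocks that
    are assigned to train/validation/test splits before windowing, so no
    context window straddles a split boundary.
    """

    lr: float = 1e-4
    weight_decay: float = 1e-2
    epochs: int = 100
    batch_size: int = 16
    lr_decay_factor: float = 0.1
    lr_decay_frac: float = 0.25  # fraction of final epochs over which lr decays
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    block_len: float | None = None  # seconds; default = one stimulus period
    unit_dropout: float = 0.0  # per-window probability of hiding each unit
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.split = tuple(self.split)

    @classmethod
    def scaled_down(cls, **overrides) -> "TrainConfig":
        base = dict(lr=1e-3, epochs=30, unit_dropout=0.25)
        base.update(overrides)
        return cls(**base)


@dataclass
class ExperimentConfig:
    """End-to-end multi-seed experiment description."""

    stimulus: str = "flash"  # {"flash", "ball"}
    flash: FlashStimulusConfig = field(default_factory=FlashStimulusConfig)
    ball: BallStimulusConfig = field(default_factory=BallStimulusConfig)
    model: ModelConfig = field(default_factory=ModelConfig.scaled_down)
    train: TrainConfig = field(default_factory=TrainConfig.scaled_down)
    n_units: int = 60
    n_informative: int | None = None
    n_seeds: int = 8
    base_seed: int = 0
    ablation_threshold: float = 0.5
    consensus_fraction: float = 0.5
    ablation_step: int = 1
    n_random_iters: int = 20
    out_dir: str = "results"

    def __post_init__(self):
        if self.stimulus not in ("flash", "ball"):
            raise ValueError("stimulus must be 'flash' or 'ball'")

    @property
    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_seeds)]


_CONFIG_TYPES = {
    "flash_stimulus": FlashStimulusConfig,
    "ball_stimulus": BallStimulusConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "experiment": ExperimentConfig,
}


def save_config(cfg, path: str | Path) -> None:
    path = Path(path)
    payload = dataclasses.asdict(cfg)
    payload["_type"] = next(k for k, v in _CONFIG_TYPES.items() if isinstance(cfg, v))
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, default=list))
    else:
        path.write_text(yaml.safe_dump(payload))


def load_config(path: str | Path):
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cls = _CONFIG_TYPES[payload.pop("_type")]
    if cls is ExperimentConfig:
        for key, sub in (("flash", FlashStimulusConfig), ("ball", BallStimulusConfig),
                         ("model", ModelConfig), ("train", TrainConfig)):
            if isinstance(payload.get(key), dict):
                payload[key] = sub(**payload[key])
    return cls(**payload)
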