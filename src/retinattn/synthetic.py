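"""Synthetic retinal recordings: stimuli, ground-truth units, Poisson spikes.

This module emulates the structure of an MEA session with a few hundred
retinal ganglion cells responding to two stimuli:

* a full-field flash (3 s ON / 3 s OFF, 10 trials) driving polarity-gated
  adaptation responses, and
* a ball moving over a 400x400 px field along a fractional Brownian motion
  trajectory (H = 0.9, mean speed 232 px/s) driving spatial Gaussian
  receptive fields.

Units carry ground-truth labels (polarity, kinetics, latency, rates, RF,
informativeness) so downstream feature extraction and attention analyses can
be validated by parameter recovery. Spikes are drawn from each unit's
inhomogeneous rate function by thinning, so spike times are continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BallStimulusConfig, FlashStimulusConfig

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusTrace",
    "GroundTruthUnit",
    "SpikeEventTable",
    "generate_flash",
    "generate_ball_trajectory",
    "fbm_increments",
    "estimate_hurst_rs",
    "generate_population",
    "simulate_spikes",
    "default_mixture",
]

# kinetics: exponential response time constant interpolates geometrically
# between a ~100 ms transient and an effectively sustained response
TAU_TRANSIENT = 0.1
TAU_SUSTAINED = 30.0


@dataclass
class StimulusTrace:
    """Uniformly sampled stimulus: 1-D intensity (flash) or 2-D position (ball)."""

    timestamps: np.ndarray
    values: np.ndarray  # (n,) for flash, (n, 2) for ball
    frame_rate: float
    kind: str  # {"flash", "ball"}
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.timestamps) / self.frame_rate

    def value_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary times."""
        t = np.asarray(t, dtype=float)
        if self.values.ndim == 1:
            return np.interp(t, self.timestamps, self.values)
        return np.stack(
            [np.interp(t, self.timestamps, self.values[:, d])
             for d in range(self.values.shape[1])], axis=-1)

    def to_csv(self, path: str | Path) -> None:
        if self.values.ndim == 1:
            df = pd.DataFrame({"t_s": self.timestamps, "value": self.values})
        else:
            df = pd.DataFrame({"t_s": self.timestamps,
                               "x_px": self.values[:, 0], "y_px": self.values[:, 1]})
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float | None = None) -> "StimulusTrace":
        df = pd.read_csv(path)
        t = df["t_s"].to_numpy()
        fr = frame_rate if frame_rate is not None else 1.0 / np.median(np.diff(t))
        if "value" in df.columns:
            return cls(t, df["value"].to_numpy(), fr, "flash")
        return cls(t, df[["x_px", "y_px"]].to_numpy(), fr, "ball")


@dataclass
class GroundTruthUnit:
    """Simulator ground truth for one retinal unit."""

    unit_id: int
    polarity: str  # {"ON", "OFF", "ON-OFF"}
    on_weight: float = 1.0  # ON/OFF mixing weight for ON-OFF units
    sustain: float = 0.5  # 0 = transient, 1 = sustained
    latency: float = 0.05  # seconds from phase onset to response
    baseline_rate: float = 1.0  # Hz
    peak_rate: float = 20.0  # Hz
    rf_center: tuple[float, float] = (200.0, 200.0)
    rf_sigma: float = 60.0  # px
    informative_gain: float = 1.0  # 0 => stimulus-independent (uninformative)

    def __post_init__(self):
        if self.polarity not in ("ON", "OFF", "ON-OFF"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not self.peak_rate >= self.baseline_rate >= 0:
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if self.informative_gain < 0:
            raise ValueError("informative_gain must be >= 0")

    @property
    def tau(self) -> float:
        return TAU_TRANSIENT * (TAU_SUSTAINED / TAU_TRANSIENT) ** self.sustain


class SpikeEventTable:
    """Continuous-time spike events from one session.

    Thin wrapper around a pandas DataFrame with columns
    ``unit_id, time_s, session_id`` plus the unit roster and session metadata.
    """

    def __init__(self, df: pd.DataFrame, roster: list[int], duration: float,
                 session_id: str = "s0", meta: dict | None = None):
        required = {"unit_id", "time_s", "session_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"spike table needs columns {sorted(required)}")
        unknown = set(df["unit_id"].unique()) - set(roster)
        if unknown:
            raise ValueError(f"spike unit ids not in roster: {sorted(unknown)[:5]}")
        self.df = df.sort_values(["unit_id", "time_s"], kind="stable").reset_index(drop=True)
        self.roster = list(roster)
        self.duration = float(duration)
        self.session_id = session_id
        self.meta = meta or {}

    def __len__(self) -> int:
        return len(self.df)

    def times_for_unit(self, unit_id: int) -> np.ndarray:
        return self.df.loc[self.df["unit_id"] == unit_id, "time_s"].to_numpy()

    def spike_counts(self) -> pd.Series:
        return self.df.groupby("unit_id").size().reindex(self.roster, fill_value=0)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_arrays(cls, unit_ids: np.ndarray, times: np.ndarray, roster: list[int],
                    duration: float, session_id: str = "s0",
                    meta: dict | None = None) -> "SpikeEventTable":
        df = pd.DataFrame({"unit_id": np.asarray(unit_ids, dtype=int),
                           "time_s": np.asarray(times, dtype=float),
                           "session_id": session_id})
        return cls(df, roster, duration, session_id, meta)

    @classmethod
    def from_csv(cls, path: str | Path, roster: list[int] | None = None,
                 duration: float | None = None) -> "SpikeEventTable":
        df = pd.read_csv(path)
        roster = roster if roster is not None else sorted(df["unit_id"].unique())
        duration = duration if duration is not None else float(df["time_s"].max()) + 1e-6
        session = df["session_id"].iloc[0] if len(df) else "s0"
        return cls(df, roster, duration, str(session))


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def generate_flash(config: FlashStimulusConfig) -> StimulusTrace:
    """Square-wave luminance trace for the repeated ON/OFF flash protocol."""
    n = int(round(config.total_duration * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    phase = np.mod(t, config.period)
    values = np.where(phase < config.on_duration,
                      config.on_intensity, config.off_intensity).astype(float)
    return StimulusTrace(t, values, config.frame_rate, "flash",
                         meta={"config": config})


def fbm_increments(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise via Davies–Harte circulant embedding.

    Returns ``n`` increments of a fractional Brownian motion with the given
    Hurst exponent and unit-variance steps; exact covariance in O(n log n).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    # first row of the circulant matrix of size 2n
    row = np.concatenate([gamma[:n], [gamma[n]], gamma[1:n][::-1]])
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)  # tiny negatives from roundoff
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    coeff = np.sqrt(eig / (2.0 * m))
    w = np.fft.fft(coeff * z)
    return np.sqrt(2.0) * w[:n].real


def generate_ball_trajectory(config: BallStimulusConfig) -> StimulusTrace:
    """2-D fBm ball trajectory, speed-calibrated and reflected at field edges.

    A single ``duration``-second trajectory is generated from two independent
    fBm paths, rescaled so the realized mean frame-to-frame speed equals
    ``target_mean_speed``, reflected into the field, and tiled for
    ``n_trials`` identical presentations.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_frames = int(round(config.duration * config.frame_rate))
    dx = fbm_increments(n_frames - 1, config.hurst, rng)
    dy = fbm_increments(n_frames - 1, config.hurst, rng)
    speed_raw = np.mean(np.hypot(dx, dy))
    scale = (config.target_mean_speed / config.frame_rate) / speed_raw
    w, h = config.field_size
    x = np.concatenate([[w / 2.0], w / 2.0 + np.cumsum(dx * scale)])
    y = np.concatenate([[h / 2.0], h / 2.0 + np.cumsum(dy * scale)])
    x = _reflect(x, w)
    y = _reflect(y, h)
    pos = np.tile(np.stack([x, y], axis=1), (config.n_trials, 1))
    t = np.arange(len(pos)) / config.frame_rate
    return StimulusTrace(t, pos, config.frame_rate, "ball",
                         meta={"config": config, "seed": config.rng_seed})


def _reflect(p: np.ndarray, size: float) -> np.ndarray:
    """Fold coordinates into [0, size] by reflection at both borders."""
    period = 2.0 * size
    q = np.mod(p, period)
    return np.where(q > size, period - q, q)


def estimate_hurst_rs(series: np.ndarray, min_window: int = 8,
                      n_scales: int = 12) -> float:
    """Hurst exponent of an increment series by rescaled-range (R/S) analysis.

    The series is partitioned into non-overlapping blocks at log-spaced block
    lengths; log(mean R/S) is regressed on log(block length) and the slope is
    returned.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 4 * min_window:
        raise ValueError("series too short for R/S analysis")
    sizes = np.unique(np.geomspace(min_window, n // 4, n_scales).astype(int))
    log_rs = []
    for size in sizes:
        n_blocks = n // size
        blocks = series[: n_blocks * size].reshape(n_blocks, size)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        cum = np.cumsum(dev, axis=1)
        r = cum.max(axis=1) - cum.min(axis=1)
        s = blocks.std(axis=1, ddof=1)
        ok = s > 0
        if not ok.any():
            continue
        log_rs.append((np.log(size), np.log(np.mean(r[ok] / s[ok]))))
    logs = np.array(log_rs)
    slope = np.polyfit(logs[:, 0], logs[:, 1], 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


def default_mixture() -> dict:
    """Default population mixture: heterogeneous polarity, kinetics and rates."""
    return {
        "polarity_probs": {"ON": 0.4, "OFF": 0.35, "ON-OFF": 0.25},
        "sustain_range": (0.0, 1.0),
        "latency_range": (0.03, 0.25),
        "baseline_rate_range": (0.2, 2.0),
        "peak_rate_range": (25.0, 50.0),
        "rf_sigma_range": (35.0, 60.0),
        "field_size": (400.0, 400.0),
        # informative units tile the field on a jittered grid so each covers
        # a distinct region and the planted labels are identifiable; set to
        # "uniform" for fully random placement
        "informative_rf_layout": "grid",
    }


def _grid_centers(n: int, field: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of n points covering the central 90% of the field."""
    w, h = field
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    xs = (np.arange(cols) + 0.5) / cols * 0.9 * w + 0.05 * w
    ys = (np.arange(rows) + 0.5) / rows * 0.9 * h + 0.05 * h
    pts = np.array([(x, y) for y in ys for x in xs])[:n]
    jitter = rng.uniform(-0.04, 0.04, size=pts.shape) * np.array([w, h])
    return pts + jitter


def generate_population(n_units: int, mixture: dict | None = None,
                        n_informative: int | None = None,
                        rng_seed: int = 0) -> list[GroundTruthUnit]:
    """Draw a labeled synthetic RGC cohort from the mixture distributions.

    Exactly ``n_informative`` units receive ``informative_gain`` 1 (the rest
    0, i.e. planted stimulus-independent units); ``None`` makes every unit
    informative.
    """
    mix = default_mixture()
    if mixture:
        mix.update(mixture)
    probs = mix["polarity_probs"]
    if not probs or abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("polarity_probs must be a non-empty distribution summing to 1")
    if n_informative is None:
        n_informative = n_units
    if n_informative > n_units:
        raise ValueError("n_informative cannot exceed n_units")
    rng = np.random.default_rng(rng_seed)
    names = list(probs)
    polarity = rng.choice(names, size=n_units, p=[probs[k] for k in names])
    informative = np.zeros(n_units)
    informative[rng.choice(n_units, size=n_informative, replace=False)] = 1.0
    w, h = mix["field_size"]
    centers = {}
    if mix.get("informative_rf_layout", "grid") == "grid" and n_informative:
        info_idx = np.flatnonzero(informative)
        for idx, c in zip(info_idx, _grid_centers(len(info_idx), (w, h), rng)):
            centers[int(idx)] = (float(c[0]), float(c[1]))
    units = []
    for i in range(n_units):
        base = rng.uniform(*mix["baseline_rate_range"])
        units.append(GroundTruthUnit(
            unit_id=i,
            polarity=str(polarity[i]),
            on_weight=float(rng.uniform(0.4, 0.6)) if polarity[i] == "ON-OFF" else 1.0,
            sustain=float(rng.uniform(*mix["sustain_range"])),
            latency=float(rng.uniform(*mix["latency_range"])),
            baseline_rate=float(base),
            peak_rate=float(base + rng.uniform(*mix["peak_rate_range"])),
            rf_center=centers.get(i, (float(rng.uniform(0, w)), float(rng.uniform(0, h)))),
            rf_sigma=float(rng.uniform(*mix["rf_sigma_range"])),
            informative_gain=float(informative[i]),
        ))
    return units


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------


def _flash_rate(unit: GroundTruthUnit, stim: StimulusTrace) -> np.ndarray:
    """Rate function for a flash session, evaluated on the frame grid.

    Each phase onset triggers an exponentially adapting response (time
    constant from the unit's sustain parameter) delayed by the unit's
    latency and truncated at the end of its phase.
    """
    cfg: FlashStimulusConfig = stim.meta["config"]
    t = stim.timestamps
    gain = unit.peak_rate - unit.baseline_rate
    lam = np.full_like(t, unit.baseline_rate)
    if gain <= 0:
        return lam
    tau = unit.tau
    phase = np.mod(t, cfg.period)
    drives = []
    if unit.polarity in ("ON", "ON-OFF"):
        weight = unit.on_weight if unit.polarity == "ON-OFF" else 1.0
        drives.append((0.0, cfg.on_duration, weight))
    if unit.polarity in ("OFF", "ON-OFF"):
        weight = (1.0 - unit.on_weight) if unit.polarity == "ON-OFF" else 1.0
        drives.append((cfg.on_duration, cfg.off_duration, weight))
    for onset, phase_dur, weight in drives:
        dt = phase - onset - unit.latency
        active = (dt >= 0) & (phase - onset < phase_dur)
        lam = lam + gain * weight * np.where(active, np.exp(-np.clip(dt, 0, None) / tau), 0.0)
    if unit.informative_gain == 0:
        return _surrogate_rate(lam, stim.frame_rate, unit.unit_id)
    return unit.baseline_rate + unit.informative_gain * (lam - unit.baseline_rate)


def _ball_rate(unit: GroundTruthUnit, stim: StimulusTrace) -> np.ndarray:
    """Rate function for a ball session: Gaussian RF drive with temporal kinetics.

    The temporal kernel is much faster than the flash adaptation constant
    (50–200 ms depending on the sustain parameter): retinal integration
    under a moving stimulus operates on the RF-crossing timescale, and a
    seconds-long kernel would destroy the spatial information the decoding
    task depends on.
    """
    gain = unit.peak_rate - unit.baseline_rate
    lam = np.full(len(stim.timestamps), unit.baseline_rate)
    if gain <= 0:
        return lam
    d2 = ((stim.values[:, 0] - unit.rf_center[0]) ** 2
          + (stim.values[:, 1] - unit.rf_center[1]) ** 2)
    drive = np.exp(-d2 / (2.0 * unit.rf_sigma**2))
    # causal exponential smoothing (area-normalized) + latency shift
    tau = 0.05 * (0.2 / 0.05) ** unit.sustain
    dt = 1.0 / stim.frame_rate
    kernel_t = np.arange(0, 5 * tau, dt)
    kernel = np.exp(-kernel_t / tau)
    kernel /= kernel.sum()
    smoothed = np.convolve(drive, kernel)[: len(drive)]
    shift = int(round(unit.latency * stim.frame_rate))
    if shift:
        smoothed = np.concatenate([np.zeros(shift), smoothed[:-shift]])
    full = lam + gain * smoothed
    if unit.informative_gain == 0:
        return _surrogate_rate(full, stim.frame_rate, unit.unit_id)
    return unit.baseline_rate + unit.informative_gain * (full - unit.baseline_rate)


def _surrogate_rate(response: np.ndarray, frame_rate: float,
                    unit_id: int, timescale: float = 0.4) -> np.ndarray:
    """Stimulus-independent rate for a planted uninformative unit.

    Matched to the mean and variance of the response the unit would have
    produced, but driven by smoothed intrinsic noise (autocorrelation time
    ``timescale``) instead of the stimulus. Only the stimulus coupling —
    not the firing statistics — distinguishes informative from
    uninformative units, which is what makes the attention-recovery test
    meaningful. The noise stream is a deterministic function of the unit id
    so the rate function itself is reproducible.
    """
    rng = np.random.default_rng(911_000_000 + unit_id)
    n = len(response)
    noise = rng.standard_normal(n)
    width = max(1, int(timescale * frame_rate))
    kt = np.arange(-3 * width, 3 * width + 1)
    kernel = np.exp(-0.5 * (kt / width) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(noise, kernel, mode="same")
    smooth /= smooth.std() or 1.0
    lam = response.mean() + response.std() * smooth
    return np.clip(lam, 0.0, None)


def rate_on_grid(unit: GroundTruthUnit, stimulus: StimulusTrace) -> np.ndarray:
    """Ground-truth λ_u(t) on the stimulus frame grid (Hz)."""
    if stimulus.kind == "flash":
        lam = _flash_rate(unit, stimulus)
    elif stimulus.kind == "ball":
        lam = _ball_rate(unit, stimulus)
    else:
        raise ValueError(f"unknown stimulus kind {stimulus.kind!r}")
    if (lam < 0).any():
        logger.warning("negative rate clamped to 0 for unit %d", unit.unit_id)
        lam = np.clip(lam, 0.0, None)
    return lam


def simulate_spikes(stimulus: StimulusTrace, units: list[GroundTruthUnit],
                    rng_seed: int = 0, session_id: str = "s0") -> SpikeEventTable:
    """Sample continuous-time spikes from each unit by Poisson thinning.

    Candidate events are drawn from a homogeneous Poisson process at the
    unit's peak rate and accepted with probability λ_u(t)/λ_max, with λ_u
    evaluated by linear interpolation of the frame-grid rate function.
    """
    rng = np.random.default_rng(rng_seed)
    duration = stimulus.duration
    all_ids, all_times = [], []
    for unit in units:
        lam = rate_on_grid(unit, stimulus)
        lam_max = float(lam.max())
        if lam_max <= 0:
            continue
        n_cand = rng.poisson(lam_max * duration)
        cand = rng.uniform(0.0, duration, size=n_cand)
        accept = rng.uniform(0.0, lam_max, size=n_cand) < np.interp(
            cand, stimulus.timestamps, lam)
        times = np.sort(cand[accept])
        all_ids.append(np.full(len(times), unit.unit_id, dtype=int))
        all_times.append(times)
    ids = np.concatenate(all_ids) if all_ids else np.array([], dtype=int)
    times = np.concatenate(all_times) if all_times else np.array([])
    return SpikeEventTable.from_arrays(
        ids, times, [u.unit_id for u in units], duration, session_id,
        meta={"stimulus": stimulus.kind, "rng_seed": rng_seed})
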