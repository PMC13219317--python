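"""Physiological light-response indices from flash responses.

For every unit the module computes, from the trial-averaged PSTH of the
repeated ON/OFF flash protocol:

* **fBR** (flash bias response) = (f_ON − f_OFF)/(f_ON + f_OFF), with f the
  peak PSTH rate within each phase; +1 pure ON, −1 pure OFF, 0 balanced
  ON-OFF.
* **Sustain index** S_i = (f_pref − f̄)/(f_pref + f̄) where f_pref is the peak
  PSTH rate in the preferred phase and f̄ the mean rate over the whole
  sequence, both in Hz; 0 for a perfectly sustained (constant-rate) unit,
  → 1 for a purely transient one. Negative values (phase peak below the
  overall mean) are reported, not clamped.
* **Latency**: onset-to-peak time within the preferred phase, reported at the
  center of the peak bin; ties broken toward the earliest bin.
* **Mean rate**: total spike count divided by total stimulus duration.

The preferred phase is the one containing the global PSTH peak (ties → ON).
Silent units yield NaN indices and are flagged rather than dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FlashStimulusConfig
from .synthetic import SpikeEventTable, StimulusTrace

__all__ = [
    "UnitPhysiology",
    "compute_psth",
    "compute_fbr",
    "compute_sustain_index",
    "compute_latency",
    "compute_mean_rate",
    "compute_population_physiology",
    "DEFAULT_BIN_S",
]

DEFAULT_BIN_S = 0.05


@dataclass
class UnitPhysiology:
    unit_id: int
    fbr: float
    sustain_index: float
    latency: float
    mean_rate: float
    psth: np.ndarray
    silent: bool = False


def _phase_masks(cfg: FlashStimulusConfig, bin_s: float):
    """Bin centers over one stimulus period and ON/OFF phase masks."""
    n_bins = int(round(cfg.period / bin_s))
    centers = (np.arange(n_bins) + 0.5) * bin_s
    on_mask = centers < cfg.on_duration
    return centers, on_mask


def compute_psth(spikes: SpikeEventTable, stimulus: StimulusTrace,
                 bin_s: float = DEFAULT_BIN_S) -> dict[int, np.ndarray]:
    """Trial-averaged firing rate (Hz) per bin over one flash period, per unit."""
    cfg: FlashStimulusConfig = stimulus.meta["config"]
    if bin_s > min(cfg.on_duration, cfg.off_duration):
        raise ValueError("PSTH bin exceeds the flash phase duration")
    if cfg.n_trials < 1:
        raise ValueError("need at least one trial")
    n_bins = int(round(cfg.period / bin_s))
    psth: dict[int, np.ndarray] = {}
    for unit_id in spikes.roster:
        t = np.mod(spikes.times_for_unit(unit_id), cfg.period)
        counts, _ = np.histogram(t, bins=n_bins, range=(0.0, cfg.period))
        psth[unit_id] = counts / (cfg.n_trials * bin_s)
    return psth


def _preferred_phase(psth: np.ndarray, on_mask: np.ndarray) -> np.ndarray:
    """Mask of the phase containing the global PSTH peak (ties -> ON)."""
    peak_on = psth[on_mask].max() if on_mask.any() else -np.inf
    peak_off = psth[~on_mask].max() if (~on_mask).any() else -np.inf
    return on_mask if peak_on >= peak_off else ~on_mask


def compute_fbr(psth: np.ndarray, on_mask: np.ndarray) -> float:
    """Flash bias response from phase-wise PSTH peaks; NaN for silent units."""
    f_on = float(psth[on_mask].max())
    f_off = float(psth[~on_mask].max())
    if f_on + f_off == 0:
        return np.nan
    return (f_on - f_off) / (f_on + f_off)


def compute_sustain_index(psth: np.ndarray, on_mask: np.ndarray) -> float:
    """Sustain index with both terms as rates; 0 for a constant-rate unit."""
    pref = _preferred_phase(psth, on_mask)
    f_pref = float(psth[pref].max())
    f_bar = float(psth.mean())
    if f_pref + f_bar == 0:
        return np.nan
    return (f_pref - f_bar) / (f_pref + f_bar)


def compute_latency(psth: np.ndarray, on_mask: np.ndarray, bin_s: float,
                    on_duration: float) -> float:
    """Onset-to-peak time (s) in the preferred phase, at the peak-bin center."""
    if psth.max() == 0 or np.ptp(psth) == 0:
        return np.nan
    pref = _preferred_phase(psth, on_mask)
    idx_in_phase = int(np.argmax(psth[pref]))  # argmax takes the earliest tie
    onset = 0.0 if pref[0] else on_duration
    first_bin = int(np.flatnonzero(pref)[0])
    return (first_bin + idx_in_phase + 0.5) * bin_s - onset


def compute_mean_rate(n_spikes: int, duration: float) -> float:
    if duration <= 0:
        raise ValueError("duration must be positive")
    return n_spikes / duration


def compute_population_physiology(spikes: SpikeEventTable, stimulus: StimulusTrace,
                                  bin_s: float = DEFAULT_BIN_S) -> pd.DataFrame:
    """All four light-response features for every unit in the roster.

    Returns a DataFrame with columns ``unit_id, fbr, sustain_index,
    latency_s, mean_rate_hz, silent``.
    """
    cfg: FlashStimulusConfig = stimulus.meta["config"]
    _, on_mask = _phase_masks(cfg, bin_s)
    psth = compute_psth(spikes, stimulus, bin_s)
    counts = spikes.spike_counts()
    rows = []
    for unit_id in spikes.roster:
        p = psth[unit_id]
        silent = p.max() == 0
        rows.append({
            "unit_id": unit_id,
            "fbr": compute_fbr(p, on_mask),
            "sustain_index": compute_sustain_index(p, on_mask),
            "latency_s": compute_latency(p, on_mask, bin_s, cfg.on_duration),
            "mean_rate_hz": compute_mean_rate(int(counts[unit_id]), spikes.duration),
            "silent": bool(silent),
        })
    return pd.DataFrame(rows)
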