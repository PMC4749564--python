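"""Unit classification by spike width, PSTHs, and rebound quantification.

Sorted spike times and mean waveforms are the inputs here; filtering
(300-6000 Hz band pass) and threshold crossing (4 SD) belong to the
upstream acquisition/sorting provenance and are not reimplemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class UnitRecord:
    """One sorted unit: per-trial spike times (s) and its mean waveform."""

    unit_id: str
    spike_times: list[np.ndarray]
    mean_waveform: np.ndarray
    sample_rate: float = 19531.25

    def __post_init__(self) -> None:
        self.spike_times = [np.asarray(t, float) for t in self.spike_times]
        for t in self.spike_times:
            if len(t) and (np.any(t < 0) or np.any(np.diff(t) < 0)):
                raise ValueError("spike times must be non-negative and sorted")
        self.mean_waveform = np.asarray(self.mean_waveform, float)

    @property
    def spike_width_ms(self) -> float:
        return spike_width(self.mean_waveform, self.sample_rate)


def spike_width(mean_waveform, sample_rate: float) -> float:
    """Trough-to-peak interval of the mean spike waveform, in ms.

    The width is the time from the waveform's global minimum to the
    subsequent global maximum.  Raises ``ValueError`` when no peak follows
    the trough (e.g. a monotone or time-reversed waveform).
    """
    wf = np.asarray(mean_waveform, float)
    if wf.ndim != 1 or len(wf) < 3:
        raise ValueError("waveform must be a 1D array with >= 3 samples")
    trough = int(np.argmin(wf))
    peak = int(np.argmax(wf))
    if peak <= trough or wf[peak] <= wf[trough]:
        raise ValueError("waveform peak must follow the trough")
    return (peak - trough) / sample_rate * 1000.0


#: spike-width class boundaries in ms; both inequalities are strict, so the
#: boundary values themselves fall in the excluded band.
FAST_SPIKING_MAX_MS = 0.35
PYRAMIDAL_MIN_MS = 0.45


def classify_unit(width_ms: float) -> str:
    """Classify a unit by trough-to-peak width.

    ``< 0.35 ms`` -> ``"fast_spiking"``; ``> 0.45 ms`` -> ``"pyramidal"``;
    intermediate widths (boundaries included) -> ``"excluded"``.
    """
    if width_ms <= 0:
        raise ValueError("spike width must be positive")
    if width_ms < FAST_SPIKING_MAX_MS:
        return "fast_spiking"
    if width_ms > PYRAMIDAL_MIN_MS:
        return "pyramidal"
    return "excluded"


@dataclass
class Psth:
    """Peristimulus time histogram: trial-averaged rate per bin (Hz)."""

    bin_edges: np.ndarray  # s, relative to the alignment event
    rates: np.ndarray      # Hz
    n_trials: int
    counts: np.ndarray = field(default=None)  # raw pooled spike counts per bin

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.rates = np.asarray(self.rates, float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mean_rate(self, window: tuple[float, float]) -> float:
        """Mean rate over bins whose centers fall inside [lo, hi)."""
        lo, hi = window
        mask = (self.bin_centers >= lo) & (self.bin_centers < hi)
        if not np.any(mask):
            raise ValueError("window contains no PSTH bins")
        return float(self.rates[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_s": self.bin_edges[:-1],
                             "bin_end_s": self.bin_edges[1:],
                             "rate_hz": self.rates})


def psth(spike_times_per_trial: Sequence[np.ndarray],
         align_times: Sequence[float] | float,
         window: tuple[float, float],
         bin_s: float = 0.1) -> Psth:
    """Trial-pooled peristimulus time histogram (default 100 ms bins).

    Spikes are re-referenced to the per-trial alignment event, counted in
    half-open bins ``[edge, next_edge)``, pooled over trials, and divided
    by ``n_trials * bin_s`` to give Hz.
    """
    trials = [np.asarray(t, float) for t in spike_times_per_trial]
    n = len(trials)
    if n == 0:
        raise ValueError("need at least one trial")
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must be ordered")
    if np.isscalar(align_times):
        align = np.full(n, float(align_times))
    else:
        align = np.asarray(align_times, float)
        if len(align) != n:
            raise ValueError("one alignment time per trial required")
    n_bins = int(np.ceil((hi - lo) / bin_s - 1e-9))
    edges = lo + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for t, a in zip(trials, align):
        rel = t - a
        idx = np.floor((rel - lo) / bin_s).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        counts += np.bincount(idx[ok], minlength=n_bins)
    rates = counts / (n * bin_s)
    return Psth(bin_edges=edges, rates=rates, n_trials=n, counts=counts)


def rebound_modulation(p: Psth,
                       baseline_window: tuple[float, float],
                       laser_window: tuple[float, float],
                       post_window: tuple[float, float]
                       ) -> tuple[Optional[float], Optional[float]]:
    """Suppression and rebound ratios relative to the baseline rate.

    ``suppression_ratio`` = mean laser-window rate / mean baseline rate;
    ``rebound_ratio`` = mean post-window rate / mean baseline rate.
    Windows must lie within the PSTH range and not overlap.  A zero
    baseline yields ``(None, None)`` with a warning.
    """
    lo, hi = p.bin_edges[0], p.bin_edges[-1]
    wins = (baseline_window, laser_window, post_window)
    for w in wins:
        if not w[0] < w[1]:
            raise ValueError("windows must be ordered")
        if w[0] < lo - 1e-9 or w[1] > hi + 1e-9:
            raise ValueError("window outside PSTH range")
    for i in range(3):
        for j in range(i + 1, 3):
            if wins[i][0] < wins[j][1] and wins[j][0] < wins[i][1]:
                raise ValueError("windows must not overlap")
    base = p.mean_rate(baseline_window)
    if base == 0:
        warnings.warn("zero baseline rate; modulation ratios undefined")
        return None, None
    return p.mean_rate(laser_window) / base, p.mean_rate(post_window) / base


def unit_table(units: Sequence[UnitRecord]) -> pd.DataFrame:
    """Per-unit width and class table."""
    rows = []
    for u in units:
        w = u.spike_width_ms
        rows.append({"unit_id": u.unit_id, "spike_width_ms": w,
                     "unit_class": classify_unit(w)})
    return pd.DataFrame(rows)
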