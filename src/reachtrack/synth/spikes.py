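"""Inhomogeneous-Poisson spike trains around an optogenetic laser window.

The rate is piecewise constant: baseline before the laser, suppressed
during it, elevated (rebound) for a fixed duration after laser offset,
then baseline again — the firing pattern characteristic of cortical units
under prolonged optogenetic inhibition of excitatory activity.
"""

from __future__ import annotations

import numpy as np

from .params import SpikeSimParams


def rate_segments(params: SpikeSimParams) -> list[tuple[float, float, float]]:
    """(t0_s, t1_s, rate_hz) segments covering [0, trial_duration_s]."""
    t_on = params.laser_window[0] / params.fps
    t_off = params.laser_window[1] / params.fps
    t_end = params.trial_duration_s
    t_rb = min(t_off + params.rebound_duration / 1000.0, t_end)
    base = params.baseline_rate
    segs = [
        (0.0, min(t_on, t_end), base),
        (min(t_on, t_end), min(t_off, t_end), base * (1.0 - params.suppression_fraction)),
        (min(t_off, t_end), t_rb, base * params.rebound_gain),
        (t_rb, t_end, base),
    ]
    out = []
    for t0, t1, r in segs:
        if r < 0:
            raise ValueError("negative firing rate")
        if t1 > t0:
            out.append((t0, t1, r))
    return out


def simulate_spike_trains(params: SpikeSimParams) -> list[np.ndarray]:
    """One sorted array of spike times (s) per trial."""
    rng = np.random.default_rng(params.seed)
    segs = rate_segments(params)
    trains = []
    for _ in range(params.n_trials):
        times = []
        for t0, t1, r in segs:
            n = rng.poisson(r * (t1 - t0))
            if n:
                times.append(rng.uniform(t0, t1, size=n))
        if times:
            trains.append(np.sort(np.concatenate(times)))
        else:
            trains.append(np.array([], dtype=float))
    return trains


def biphasic_waveform(trough_to_peak_ms: float, sample_rate: float = 19531.25,
                      amplitude_uv: float = 80.0, n_samples: int = 64,
                      trough_at: int = 20) -> np.ndarray:
    """Synthetic mean spike waveform with a controlled trough-to-peak width.

    A negative Gaussian trough followed by a positive Gaussian peak,
    suitable for exercising spike-width classification.
    """
    peak_at = trough_at + max(1, int(round(trough_to_peak_ms * sample_rate / 1000.0)))
    if peak_at >= n_samples:
        raise ValueError("waveform too short for requested width")
    t = np.arange(n_samples)
    w = trough_to_peak_ms * sample_rate / 1000.0
    wf = (-amplitude_uv * np.exp(-0.5 * ((t - trough_at) / (0.25 * w + 1.0)) ** 2)
          + 0.5 * amplitude_uv * np.exp(-0.5 * ((t - peak_at) / (0.35 * w + 1.0)) ** 2))
    return wf
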