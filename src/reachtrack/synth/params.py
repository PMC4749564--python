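"""Parameter blocks for the synthetic-data generator.

Defaults describe a head-fixed mouse prehension setup: a ~12 mm reach from
the perch to a food pellet and back up to the mouth, filmed at 500 frames/s
on two perpendicular 352 x 260 px cameras, with optogenetic laser windows
that freeze movement at short latency and can evoke a rebound reach at
laser offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..stereo import StereoRig, default_rig

#: Default per-epoch durations in ms (means of the log-normal draw).
DEFAULT_EPOCH_DURATIONS = {
    "Lift": 100.0,
    "HandOpen": 120.0,
    "Grab": 80.0,
    "Supinate": 100.0,
    "AtMouth": 200.0,
    "Chew": 800.0,
}


@dataclass
class ReachKinematicsParams:
    """Geometry and timing of an unperturbed cued reach.

    Positions are in mm in the world frame (origin at the perch); durations
    in ms.  ``epoch_duration_cv`` is the coefficient of variation of the
    log-normal duration draw.  ``position_noise_sd`` is iid Gaussian noise
    added to the hand path per frame and axis.
    """

    perch_pos: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pellet_pos: np.ndarray = field(default_factory=lambda: np.array([10.0, 6.0, -2.0]))
    mouth_pos: np.ndarray = field(default_factory=lambda: np.array([1.0, 3.0, 7.0]))
    epoch_duration_means: dict = field(default_factory=lambda: dict(DEFAULT_EPOCH_DURATIONS))
    epoch_duration_cv: float = 0.08
    position_noise_sd: float = 0.15
    fps: float = 500.0
    first_lift_latency_mean_control: float = 400.0
    first_lift_latency_sd_control: float = 120.0

    def __post_init__(self) -> None:
        self.perch_pos = np.asarray(self.perch_pos, float).reshape(3)
        self.pellet_pos = np.asarray(self.pellet_pos, float).reshape(3)
        self.mouth_pos = np.asarray(self.mouth_pos, float).reshape(3)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if any(v <= 0 for v in self.epoch_duration_means.values()):
            raise ValueError("epoch durations must be positive")
        if self.epoch_duration_cv < 0 or self.position_noise_sd < 0:
            raise ValueError("spreads must be non-negative")
        pts = [self.perch_pos, self.pellet_pos, self.mouth_pos]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("perch, pellet and mouth must be pairwise distinct")


@dataclass
class PerturbationParams:
    """Optogenetic laser window and its behavioral consequences.

    ``laser_on`` is a frame index; ``laser_duration`` in ms.  Movement in
    progress freezes after a latency drawn uniformly from
    ``freeze_latency_range`` (ms).  After laser offset a rebound reach
    occurs with probability looked up (with linear interpolation) in
    ``rebound_prob_vs_duration``, starting after a Normal(mean, sd) latency.
    """

    laser_on: int = 500
    laser_duration: float = 2000.0
    freeze_latency_range: tuple[float, float] = (72.0, 170.0)
    retraction_probability: float = 0.0
    rebound_prob_vs_duration: dict = field(
        default_factory=lambda: {500.0: 0.2, 1000.0: 0.5, 2000.0: 0.9, 4000.0: 0.95})
    rebound_latency_mean: float = 250.0
    rebound_latency_sd: float = 50.0
    rebound_offset_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rebound_offset_mm = np.asarray(self.rebound_offset_mm, float).reshape(3)
        lo, hi = self.freeze_latency_range
        if not lo <= hi:
            raise ValueError("freeze_latency_range must be ordered")
        if not 0.0 <= self.retraction_probability <= 1.0:
            raise ValueError("retraction_probability must be in [0, 1]")
        for p in self.rebound_prob_vs_duration.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("rebound probabilities must be in [0, 1]")
        if self.laser_duration <= 0:
            raise ValueError("laser_duration must be positive")

    def rebound_probability(self) -> float:
        """Rebound probability for this laser duration (linear interpolation, clamped)."""
        items = sorted((float(k), float(v)) for k, v in self.rebound_prob_vs_duration.items())
        ds = np.array([d for d, _ in items])
        ps = np.array([p for _, p in items])
        return float(np.interp(self.laser_duration, ds, ps))


@dataclass
class SceneParams:
    """Rendering of the hand as a Gaussian blob in two camera views."""

    image_size: tuple[int, int] = (352, 260)  # (width, height) px
    blob_sigma: float = 6.0
    blob_amplitude: float = 150.0
    background_noise_sd: float = 8.0
    cameras: StereoRig = field(default_factory=default_rig)

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image_size must be positive")
        if self.blob_sigma <= 0:
            raise ValueError("blob_sigma must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")


@dataclass
class SpikeSimParams:
    """Inhomogeneous-Poisson spike trains around a laser window.

    Rates in Hz; the laser window is in frames at ``fps``; trains are
    simulated over ``[0, trial_duration_s]`` seconds per trial.  During the
    laser the rate is ``baseline_rate * (1 - suppression_fraction)``; for
    ``rebound_duration`` ms after laser offset it is
    ``baseline_rate * rebound_gain``.
    """

    baseline_rate: float = 10.0
    suppression_fraction: float = 0.9
    rebound_gain: float = 3.0
    rebound_duration: float = 200.0
    laser_window: tuple[int, int] = (500, 1500)
    n_trials: int = 100
    seed: int = 0
    fps: float = 500.0
    trial_duration_s: float = 6.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must be in [0, 1]")
        if self.rebound_gain < 1.0:
            raise ValueError("rebound_gain must be >= 1")
        lo, hi = self.laser_window
        if not lo < hi:
            raise ValueError("laser_window must be ordered")
        if self.trial_duration_s <= 0 or self.fps <= 0:
            raise ValueError("durations and fps must be positive")
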