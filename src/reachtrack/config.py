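"""Run configuration schema (validated, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

STAGES = ("generate", "track", "reconstruct", "analyze", "report")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthBlock(_Strict):
    seed: int = 0
    n_trials: int = 40
    laser_fraction: float = 0.2
    n_frames: int = 3000
    laser_align_epoch: Optional[str] = "Lift"
    laser_duration_ms: float = 2000.0
    n_rebound_trials: int = 20
    render_trials: int = 1
    render_frames: int = 400
    position_noise_sd_mm: float = 0.15
    first_lift_latency_mean_ms: float = 400.0
    first_lift_latency_sd_ms: float = 120.0
    rebound_latency_mean_ms: float = 250.0
    rebound_latency_sd_ms: float = 50.0


class TrackerBlock(_Strict):
    seed: int = 1
    n_stages: int = 100
    n_ferns: int = 50
    fern_depth: int = 5
    n_candidate_features: int = 400
    n_selected_features: int = 40
    feature_radius: float = 60.0
    augmentations_per_frame: int = 10
    n_train_frames: int = 200
    n_inits: int = 50
    smoothness_weight: float = 0.01
    mode_bandwidth: float = 5.0
    error_spread_threshold: float = 0.4


class StereoBlock(_Strict):
    seed: int = 2
    calibration_file: Optional[str] = None
    refine: bool = False
    refine_intrinsics: bool = False


class AnalysisBlock(_Strict):
    seed: int = 3
    horizon_ms: float = 400.0
    initiation_window_frames: tuple[int, int] = (0, 1000)
    nn_checkpoint: float = 1.0


class EphysBlock(_Strict):
    seed: int = 4
    baseline_rate_hz: float = 10.0
    suppression_fraction: float = 0.9
    rebound_gain: float = 3.0
    rebound_duration_ms: float = 200.0
    n_trials: int = 100
    laser_window_frames: tuple[int, int] = (500, 1500)
    trial_duration_s: float = 6.0


class RunConfig(_Strict):
    """Full pipeline configuration; every stochastic stage has its own seed."""

    outdir: str = "runs/out"
    fps: float = 500.0
    stages: list[str] = list(STAGES)
    synth: SynthBlock = SynthBlock()
    tracker: TrackerBlock = TrackerBlock()
    stereo: StereoBlock = StereoBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    ephys: EphysBlock = EphysBlock()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return sorted(set(v), key=STAGES.index)

    def config_hash(self) -> str:
        # outdir is a location, not a parameter: runs of the same analysis
        # into different directories hash identically
        payload = json.dumps(self.model_dump(exclude={"outdir"}),
                             sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        """Derive a config whose per-stage seeds are offset from one master seed."""
        c = self.model_copy(deep=True)
        c.synth.seed = seed % (2 ** 31)
        c.tracker.seed = (seed + 1) % (2 ** 31)
        c.stereo.seed = (seed + 2) % (2 ** 31)
        c.analysis.seed = (seed + 3) % (2 ** 31)
        c.ephys.seed = (seed + 4) % (2 ** 31)
        return c

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(exclude={"outdir"}), fh, sort_keys=False)
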