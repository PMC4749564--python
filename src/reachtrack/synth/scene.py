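"""Rendering of stereo video frames from a simulated trial.

Each frame shows the hand as an isotropic Gaussian intensity blob centered
on the projection of the 3D hand position through the corresponding camera,
over a noisy background — a deliberately minimal stand-in for near-infrared
video of a reaching forelimb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ..ethogram import Trial
from ..stereo import project_point
from .params import SceneParams

VIEWS = ("front", "side")


@dataclass
class RenderedVideo:
    """Frame stacks plus ground-truth 2D tracks for both views."""

    frames: dict[str, np.ndarray]          # view -> (n, h, w) float32 in [0, 255]
    tracks: dict[str, np.ndarray]          # view -> (n, 2) px ground truth
    warnings: list[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return next(iter(self.frames.values())).shape[0]


def render_stereo_video(trial: Trial, scene: SceneParams, seed: int = 0) -> RenderedVideo:
    """Render both camera views of a trial's 3D hand trajectory.

    Frames where the hand projects outside the image bounds are still
    rendered (the blob is clipped) and recorded in ``warnings``.
    """
    if trial.trajectory3d is None:
        raise ValueError("trial has no 3D trajectory to render")
    traj = np.asarray(trial.trajectory3d, float)
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory must be defined (finite) at every frame")
    rng = np.random.default_rng(seed)
    w, h = scene.image_size
    n = len(traj)
    cams = {"front": scene.cameras.front, "side": scene.cameras.side}

    frames: dict[str, np.ndarray] = {}
    tracks: dict[str, np.ndarray] = {}
    warn: list[dict] = []
    half = int(np.ceil(4 * scene.blob_sigma))
    for view, cam in cams.items():
        uv = project_point(traj, cam)
        tracks[view] = uv
        stack = np.zeros((n, h, w), dtype=np.float32)
        if scene.background_noise_sd > 0:
            stack += rng.normal(0.0, scene.background_noise_sd,
                                size=stack.shape).astype(np.float32)
        for i, (u, v) in enumerate(uv):
            if not (0 <= u < w and 0 <= v < h):
                warn.append({"view": view, "frame": i,
                             "reason": "hand projects outside image bounds",
                             "u": float(u), "v": float(v)})
            x0 = max(0, int(np.floor(u)) - half)
            x1 = min(w, int(np.ceil(u)) + half + 1)
            y0 = max(0, int(np.floor(v)) - half)
            y1 = min(h, int(np.ceil(v)) + half + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-0.5 * ((xs - u) / scene.blob_sigma) ** 2)
            gy = np.exp(-0.5 * ((ys - v) / scene.blob_sigma) ** 2)
            stack[i, y0:y1, x0:x1] += scene.blob_amplitude * np.outer(gy, gx).astype(np.float32)
        np.clip(stack, 0.0, 255.0, out=stack)
        frames[view] = stack
    return RenderedVideo(frames=frames, tracks=tracks, warnings=warn)


def write_video(video: RenderedVideo, outdir, trial_id: str, seed: int | None = None) -> Path:
    """Write per-view PNG frame stacks, ground-truth track CSVs and a manifest."""
    outdir = Path(outdir)
    for view in VIEWS:
        vdir = outdir / trial_id / view
        vdir.mkdir(parents=True, exist_ok=True)
        stack = video.frames[view]
        for i in range(stack.shape[0]):
            iio.imwrite(vdir / f"frame_{i:06d}.png",
                        stack[i].round().astype(np.uint8))
    rows = {"frame": np.arange(video.n_frames)}
    for view in VIEWS:
        rows[f"x_px_{view}"] = video.tracks[view][:, 0]
        rows[f"y_px_{view}"] = video.tracks[view][:, 1]
    pd.DataFrame(rows).to_csv(outdir / trial_id / "ground_truth_tracks.csv", index=False)
    manifest = {
        "trial_id": trial_id, "seed": seed,
        "n_frames": video.n_frames,
        "views": list(VIEWS),
        "n_warnings": len(video.warnings),
        "warnings": video.warnings[:100],
    }
    with open(outdir / trial_id / "render_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir / trial_id


def read_frame_stack(view_dir) -> np.ndarray:
    """Read a zero-padded PNG frame directory back into an (n, h, w) stack."""
    paths = sorted(Path(view_dir).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frames found in {view_dir}")
    return np.stack([iio.imread(p).astype(np.float32) for p in paths])
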