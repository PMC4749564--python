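"""Cascaded Pose Regression hand tracker.

The tracker converts a grayscale video frame into a 2D hand-position
estimate.  A cascade of random-fern regressors, each operating on
pose-indexed features (differences of pixel intensities sampled at offsets
relative to the current pose estimate), iteratively moves an initial pose
guess toward the hand.  At track time the cascade is run from many random
initializations; the final estimates are clustered by mean shift, and the
densest mode is the frame's estimate, with the fraction of initializations
that landed in it serving as the confidence.  A dynamic-programming pass
then selects one candidate mode per frame to form a temporally smooth
trajectory, flags frames that look unreliable, and re-tracks them from
their smoothed neighbors.  Manual corrections can be pinned into the
trajectory and the smoothing re-run around them.

Coordinates are 0-based pixels, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "PoseEstimate", "TrackConfig", "FernStage", "CascadeTracker",
    "TrackResult", "pose_indexed_features", "cluster_modes",
    "smooth_track", "select_modes_dp", "apply_corrections",
]


@dataclass
class PoseEstimate:
    """Tracked hand position for one frame, with confidence in [0, 1]."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class TrackConfig:
    """Track-time configuration.

    ``n_inits`` random initializations per frame; ``smoothness_weight`` is
    the quadratic jump penalty (per px^2) in the smoothing objective;
    ``mode_bandwidth`` the mean-shift kernel bandwidth in px;
    ``error_spread_threshold`` the minimum weight fraction of the selected
    mode below which a frame is flagged; ``jump_limit_px`` the largest
    accepted frame-to-frame displacement before flagging.
    """

    n_inits: int = 50
    smoothness_weight: float = 0.01
    mode_bandwidth: float = 5.0
    error_spread_threshold: float = 0.4
    jump_limit_px: float = 25.0
    max_passes: int = 2

    def __post_init__(self) -> None:
        if self.n_inits < 1:
            raise ValueError("n_inits must be >= 1")
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be >= 0")
        if not 0.0 <= self.error_spread_threshold <= 1.0:
            raise ValueError("error_spread_threshold must be in [0, 1]")


def _sample_intensity(images: np.ndarray, frame_idx: np.ndarray,
                      x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Clamped nearest-pixel intensity lookup. images: (F, H, W)."""
    h, w = images.shape[1:]
    xi = np.clip(np.rint(x).astype(np.intp), 0, w - 1)
    yi = np.clip(np.rint(y).astype(np.intp), 0, h - 1)
    return images[frame_idx, yi, xi]


def _features(images: np.ndarray, frame_idx: np.ndarray, poses: np.ndarray,
              offsets: np.ndarray) -> np.ndarray:
    """Pose-indexed intensity-difference features.

    offsets: (F, 4) columns (dxA, dyA, dxB, dyB); returns (N, F).
    """
    x = poses[:, 0][:, None]
    y = poses[:, 1][:, None]
    fa = _sample_intensity(images, frame_idx[:, None], x + offsets[None, :, 0],
                           y + offsets[None, :, 1])
    fb = _sample_intensity(images, frame_idx[:, None], x + offsets[None, :, 2],
                           y + offsets[None, :, 3])
    return fa - fb


def pose_indexed_features(image: np.ndarray, pose, feature_defs) -> np.ndarray:
    """Intensity differences at offsets indexed to the current pose.

    ``feature_defs`` is a sequence of offset pairs
    ``((dxA, dyA), (dxB, dyB))`` or an (F, 4) array; feature i is the
    intensity at ``pose + offsetA_i`` minus the intensity at
    ``pose + offsetB_i``, with out-of-bounds samples clamped to the nearest
    pixel.
    """
    defs = np.asarray([np.concatenate([np.asarray(a, float).ravel(),
                                       np.asarray(b, float).ravel()])
                       for a, b in feature_defs]) \
        if not isinstance(feature_defs, np.ndarray) else np.asarray(feature_defs, float)
    if defs.size == 0:
        raise ValueError("feature_defs must not be empty")
    defs = defs.reshape(-1, 4)
    pose = np.asarray(pose, float)
    if not np.all(np.isfinite(pose)):
        raise ValueError("pose must be finite")
    img = np.asarray(image, float)[None]
    poses = pose[None, :]
    return _features(img, np.zeros(1, dtype=np.intp), poses, defs)[0]


@dataclass
class FernStage:
    """One cascade stage: selected features, fern tests and bin outputs."""

    offsets: np.ndarray        # (n_sel, 4) pose-indexed offset pairs
    fern_features: np.ndarray  # (n_ferns, depth) indices into offsets
    thresholds: np.ndarray     # (n_ferns, depth)
    outputs: np.ndarray        # (n_ferns, 2**depth, 2) displacement in px

    def predict(self, phi: np.ndarray) -> np.ndarray:
        """Average displacement over ferns; phi: (N, n_sel) feature matrix."""
        n = phi.shape[0]
        depth = self.fern_features.shape[1]
        powers = 1 << np.arange(depth)
        delta = np.zeros((n, 2))
        for f in range(self.fern_features.shape[0]):
            bits = phi[:, self.fern_features[f]] > self.thresholds[f]
            idx = bits @ powers
            delta += self.outputs[f, idx]
        return delta / self.fern_features.shape[0]


class CascadeTracker(BaseEstimator):
    """Cascaded Pose Regression with random-fern stages.

    A scikit-learn style estimator: ``fit(frames, labels)`` trains the
    cascade from labeled frames, ``predict(frames)`` returns smoothed
    per-frame pose estimates.  Fitted attributes carry a trailing
    underscore.

    Parameters
    ----------
    n_stages : int
        Number of cascade iterations T (default 100).
    n_ferns, fern_depth : int
        Random ferns per stage and binary tests per fern.
    n_candidate_features : int
        Size of the random pose-indexed feature pool per stage, from which
        the features most correlated with the residual displacement are
        selected.
    n_selected_features : int
        Features kept per stage (shared by the stage's ferns).
    feature_radius : float
        Maximum offset of a feature sample from the current pose, px.
    augmentations_per_frame : int
        Training poses generated per labeled frame: half perturbed around
        the label, half uniform over the image.
    shrinkage : float
        Additive regularizer on fern-bin counts.
    """

    def __init__(self, n_stages: int = 100, n_ferns: int = 50, fern_depth: int = 5,
                 n_candidate_features: int = 400, n_selected_features: int = 40,
                 feature_radius: float = 60.0, augmentations_per_frame: int = 10,
                 perturb_sd: float = 20.0, shrinkage: float = 5.0,
                 random_state: Optional[int] = None):
        self.n_stages = n_stages
        self.n_ferns = n_ferns
        self.fern_depth = fern_depth
        self.n_candidate_features = n_candidate_features
        self.n_selected_features = n_selected_features
        self.feature_radius = feature_radius
        self.augmentations_per_frame = augmentations_per_frame
        self.perturb_sd = perturb_sd
        self.shrinkage = shrinkage
        self.random_state = random_state

    # ------------------------------------------------------------------
    # training

    def fit(self, frames: Sequence[np.ndarray], labels) -> "CascadeTracker":
        """Train the cascade on labeled frames.

        ``frames``: list of equally-sized grayscale images; ``labels``:
        (n, 2) hand positions in px, one per frame, inside image bounds.
        """
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        images = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
        labels = np.asarray(labels, dtype=float)
        if images.ndim != 3:
            raise ValueError("frames must be single-channel 2D images")
        if len(labels) != len(images):
            raise ValueError("one label per frame required")
        if len(images) < 10:
            raise ValueError("need at least 10 labeled frames")
        h, w = images.shape[1:]
        if np.any(labels[:, 0] < 0) or np.any(labels[:, 0] >= w) \
                or np.any(labels[:, 1] < 0) or np.any(labels[:, 1] >= h):
            raise ValueError("labels must lie inside image bounds")
        if np.allclose(labels, labels[0]):
            warnings.warn("all labels identical; the trained model is degenerate")
        rng = np.random.default_rng(self.random_state)

        n_img = len(images)
        a = max(2, self.augmentations_per_frame)
        frame_idx = np.repeat(np.arange(n_img, dtype=np.intp), a)
        targets = labels[frame_idx]
        n_samp = len(frame_idx)
        poses = np.empty((n_samp, 2))
        near = rng.random(n_samp) < 0.5
        poses[near] = targets[near] + rng.normal(0, self.perturb_sd, (near.sum(), 2))
        n_far = (~near).sum()
        poses[~near] = np.column_stack([rng.uniform(0, w - 1, n_far),
                                        rng.uniform(0, h - 1, n_far)])
        np.clip(poses[:, 0], 0, w - 1, out=poses[:, 0])
        np.clip(poses[:, 1], 0, h - 1, out=poses[:, 1])

        stages: list[FernStage] = []
        history = []
        depth = self.fern_depth
        for _ in range(self.n_stages):
            residual = targets - poses
            history.append(float(np.median(np.linalg.norm(residual, axis=1))))
            # random pose-indexed feature pool
            pool = self._random_offsets(rng, self.n_candidate_features)
            phi = _features(images, frame_idx, poses, pool)
            # correlation-based selection against the residual displacement
            phic = phi - phi.mean(axis=0)
            sd = phic.std(axis=0) + 1e-9
            rc = residual - residual.mean(axis=0)
            rsd = rc.std(axis=0) + 1e-9
            corr = np.abs(phic.T @ rc) / (len(phi) * sd[:, None] * rsd[None, :])
            score = corr.max(axis=1)
            sel = np.argsort(score)[::-1][:self.n_selected_features]
            offsets = pool[sel]
            phi_sel = phi[:, sel]

            fern_features = np.empty((self.n_ferns, depth), dtype=np.intp)
            thresholds = np.empty((self.n_ferns, depth))
            outputs = np.zeros((self.n_ferns, 2 ** depth, 2))
            powers = 1 << np.arange(depth)
            delta = np.zeros((n_samp, 2))
            for f in range(self.n_ferns):
                feats = rng.choice(len(sel), size=depth, replace=False)
                fern_features[f] = feats
                lo = np.percentile(phi_sel[:, feats], 20, axis=0)
                hi = np.percentile(phi_sel[:, feats], 80, axis=0)
                thresholds[f] = rng.uniform(lo, hi + 1e-6)
                bits = phi_sel[:, feats] > thresholds[f]
                idx = bits @ powers
                counts = np.bincount(idx, minlength=2 ** depth).astype(float)
                sums = np.zeros((2 ** depth, 2))
                np.add.at(sums, idx, residual)
                outputs[f] = sums / (counts + self.shrinkage)[:, None]
                delta += outputs[f, idx]
            poses = poses + delta / self.n_ferns
            np.clip(poses[:, 0], 0, w - 1, out=poses[:, 0])
            np.clip(poses[:, 1], 0, h - 1, out=poses[:, 1])
            stages.append(FernStage(offsets=offsets, fern_features=fern_features,
                                    thresholds=thresholds, outputs=outputs))
        residual = targets - poses
        history.append(float(np.median(np.linalg.norm(residual, axis=1))))

        self.stages_ = stages
        self.training_history_ = np.asarray(history)
        self.image_shape_ = (h, w)
        self.training_metadata_ = {
            "n_frames": n_img, "n_samples": n_samp,
            "final_median_error_px": history[-1],
        }
        return self

    def _random_offsets(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Offset pairs in the disk of radius feature_radius.

        Radii are drawn as ``feature_radius * u^2`` so the pool mixes
        coarse, long-range features (useful far from the hand) with many
        short-range ones (needed for sub-blob localization late in the
        cascade); the correlation-based selection picks whichever scale
        matches the current residuals.
        """
        out = np.empty((n, 4))
        for col in (0, 2):
            r = self.feature_radius * rng.random(n) ** 2
            th = rng.uniform(0, 2 * np.pi, n)
            out[:, col] = r * np.cos(th)
            out[:, col + 1] = r * np.sin(th)
        return np.rint(out)

    # ------------------------------------------------------------------
    # tracking

    def _check_fitted(self) -> None:
        if not hasattr(self, "stages_"):
            raise RuntimeError("tracker is not fitted")

    def run_cascade(self, images: np.ndarray, frame_idx: np.ndarray,
                    poses: np.ndarray) -> np.ndarray:
        """Run all cascade stages on a batch of (frame, pose) samples."""
        self._check_fitted()
        h, w = images.shape[1:]
        poses = poses.copy()
        for stage in self.stages_:
            phi = _features(images, frame_idx, poses, stage.offsets)
            poses += stage.predict(phi)
            np.clip(poses[:, 0], 0, w - 1, out=poses[:, 0])
            np.clip(poses[:, 1], 0, h - 1, out=poses[:, 1])
        return poses

    def track_frame(self, image: np.ndarray, cfg: TrackConfig | None = None,
                    seed: int = 0, init_poses: Optional[np.ndarray] = None):
        """Candidate modes for a single frame, sorted by weight."""
        cfg = cfg or TrackConfig()
        image = np.asarray(image, dtype=np.float32)
        h, w = image.shape
        rng = np.random.default_rng(seed)
        if init_poses is None:
            init_poses = np.column_stack([rng.uniform(0, w - 1, cfg.n_inits),
                                          rng.uniform(0, h - 1, cfg.n_inits)])
        finals = self.run_cascade(image[None], np.zeros(len(init_poses), dtype=np.intp),
                                  init_poses)
        return cluster_modes(finals, cfg.mode_bandwidth)

    def track_video(self, frames, cfg: TrackConfig | None = None, seed: int = 0):
        """Track every frame and smooth; returns a :class:`TrackResult`.

        Runs the multi-pass procedure: per-frame multi-initialization
        tracking, mean-shift mode extraction, DP smoothing, then re-tracking
        of flagged frames initialized from their smoothed neighbors.
        """
        cfg = cfg or TrackConfig()
        images = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
        modes = self._track_all(images, cfg, seed)
        return smooth_track(modes, cfg, frames=images, model=self, seed=seed + 1)

    def _track_all(self, images: np.ndarray, cfg: TrackConfig, seed: int):
        n, h, w = images.shape
        rng = np.random.default_rng(seed)
        k = cfg.n_inits
        frame_idx = np.repeat(np.arange(n, dtype=np.intp), k)
        poses = np.column_stack([rng.uniform(0, w - 1, n * k),
                                 rng.uniform(0, h - 1, n * k)])
        finals = self.run_cascade(images, frame_idx, poses)
        return [cluster_modes(finals[i * k:(i + 1) * k], cfg.mode_bandwidth)
                for i in range(n)]

    # ------------------------------------------------------------------
    # serialization

    def to_json(self, path) -> None:
        self._check_fitted()
        doc = {
            "format": "reachtrack-cascade", "version": 1,
            "params": self.get_params(),
            "image_shape": list(self.image_shape_),
            "training_metadata": self.training_metadata_,
            "training_history": self.training_history_.tolist(),
            "stages": [{
                "offsets": s.offsets.tolist(),
                "fern_features": s.fern_features.tolist(),
                "thresholds": s.thresholds.tolist(),
                "outputs": s.outputs.tolist(),
            } for s in self.stages_],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "CascadeTracker":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "reachtrack-cascade":
            raise ValueError("not a cascade model file")
        model = cls(**doc["params"])
        model.stages_ = [FernStage(
            offsets=np.asarray(s["offsets"]),
            fern_features=np.asarray(s["fern_features"], dtype=np.intp),
            thresholds=np.asarray(s["thresholds"]),
            outputs=np.asarray(s["outputs"]),
        ) for s in doc["stages"]]
        model.training_history_ = np.asarray(doc["training_history"])
        model.image_shape_ = tuple(doc["image_shape"])
        model.training_metadata_ = doc["training_metadata"]
        return model


# ---------------------------------------------------------------------------
# mode clustering


def cluster_modes(points: np.ndarray, bandwidth: float,
                  max_iter: int = 100, tol: float = 1e-3) -> list[tuple[np.ndarray, float]]:
    """Mean-shift clustering of final cascade estimates.

    Returns ``(position, weight)`` modes sorted by decreasing weight (ties
    broken by lowest (y, x)); weights are counts of converged points, so
    ``weight / n_points`` is a density fraction.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    y = pts.copy()
    for _ in range(max_iter):
        d2 = ((y[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        wgt = np.exp(-0.5 * d2 / bandwidth ** 2)
        new = (wgt @ pts) / wgt.sum(axis=1, keepdims=True)
        if np.abs(new - y).max() < tol:
            y = new
            break
        y = new
    # merge converged points within bandwidth / 2
    modes: list[tuple[np.ndarray, float]] = []
    assigned = np.full(n, -1)
    for i in range(n):
        for m, (pos, _) in enumerate(modes):
            if np.linalg.norm(y[i] - pos) < bandwidth / 2:
                assigned[i] = m
                break
        if assigned[i] < 0:
            modes.append((y[i].copy(), 0.0))
            assigned[i] = len(modes) - 1
    out = []
    for m, (pos, _) in enumerate(modes):
        members = assigned == m
        out.append((y[members].mean(axis=0), float(members.sum())))
    out.sort(key=lambda t: (-t[1], t[0][1], t[0][0]))
    return out


# ---------------------------------------------------------------------------
# smoothing


@dataclass
class TrackResult:
    """Smoothed trajectory plus the per-frame candidate modes it came from."""

    estimates: list[PoseEstimate]
    flagged: list[int]
    modes: list[list[tuple[np.ndarray, float]]]
    image_shape: Optional[tuple[int, int]] = None
    pinned: dict = field(default_factory=dict)

    def positions(self) -> np.ndarray:
        return np.array([[e.x, e.y] for e in self.estimates])

    def confidences(self) -> np.ndarray:
        return np.array([e.confidence for e in self.estimates])


def select_modes_dp(per_frame_modes, smoothness_weight: float,
                    pinned: Optional[dict] = None) -> list[int]:
    """Viterbi selection of one mode per frame.

    Minimizes ``sum_t [-log(weight_fraction_t) + lambda * ||p_t - p_{t-1}||^2]``
    over all mode assignments.  ``pinned`` maps frame -> mode index that must
    be chosen.
    """
    if not per_frame_modes:
        raise ValueError("empty mode sequence")
    pinned = pinned or {}
    n = len(per_frame_modes)
    costs = []
    positions = []
    for t, modes in enumerate(per_frame_modes):
        if not modes:
            raise ValueError(f"frame {t} has no candidate modes")
        total = sum(wgt for _, wgt in modes)
        c = np.array([-np.log(max(wgt / total, 1e-12)) for _, wgt in modes])
        if t in pinned:
            mask = np.full(len(modes), np.inf)
            mask[pinned[t]] = 0.0
            c = c + mask
        costs.append(c)
        positions.append(np.array([pos for pos, _ in modes]))

    acc = costs[0].copy()
    back: list[np.ndarray] = []
    for t in range(1, n):
        d2 = ((positions[t][:, None, :] - positions[t - 1][None, :, :]) ** 2).sum(-1)
        trans = acc[None, :] + smoothness_weight * d2
        best_prev = trans.argmin(axis=1)
        back.append(best_prev)
        acc = costs[t] + trans[np.arange(len(costs[t])), best_prev]
    sel = [int(acc.argmin())]
    for t in range(n - 2, -1, -1):
        sel.append(int(back[t][sel[-1]]))
    return sel[::-1]


def _flag_frames(per_frame_modes, selection, cfg: TrackConfig,
                 pinned: Optional[dict] = None) -> list[int]:
    pinned = pinned or {}
    flags = []
    prev = None
    for t, (modes, m) in enumerate(zip(per_frame_modes, selection)):
        pos, wgt = modes[m]
        total = sum(w for _, w in modes)
        if t in pinned:
            prev = pos
            continue
        bad = wgt / total < cfg.error_spread_threshold
        if prev is not None and np.linalg.norm(pos - prev) > cfg.jump_limit_px:
            bad = True
        if bad:
            flags.append(t)
        prev = pos
    return flags


def smooth_track(per_frame_modes, cfg: TrackConfig | None = None,
                 frames: Optional[np.ndarray] = None,
                 model: Optional[CascadeTracker] = None,
                 seed: int = 0,
                 pinned: Optional[dict] = None) -> TrackResult:
    """DP-smooth candidate modes into a trajectory and flag doubtful frames.

    With ``frames`` and ``model`` supplied, flagged frames are re-tracked in
    a second pass with initializations drawn around the interpolation of
    their smoothed unflagged neighbors, and the DP is re-run.
    """
    cfg = cfg or TrackConfig()
    if not per_frame_modes:
        raise ValueError("empty mode sequence")
    modes = [list(m) for m in per_frame_modes]
    pinned = dict(pinned or {})

    selection = select_modes_dp(modes, cfg.smoothness_weight, pinned)
    flags = _flag_frames(modes, selection, cfg, pinned)

    passes = cfg.max_passes - 1 if (frames is not None and model is not None) else 0
    rng = np.random.default_rng(seed)
    for _ in range(passes):
        if not flags:
            break
        positions = np.array([modes[t][m][0] for t, m in enumerate(selection)])
        good = np.array([t for t in range(len(modes)) if t not in flags])
        for t in flags:
            if len(good):
                # interpolate the smoothed track over unflagged neighbors
                ref = np.array([np.interp(t, good, positions[good][:, 0]),
                                np.interp(t, good, positions[good][:, 1])])
            else:
                ref = positions[t]
            h, w = frames[t].shape
            inits = ref[None, :] + rng.normal(0, 2 * cfg.mode_bandwidth,
                                              (cfg.n_inits, 2))
            np.clip(inits[:, 0], 0, w - 1, out=inits[:, 0])
            np.clip(inits[:, 1], 0, h - 1, out=inits[:, 1])
            modes[t] = model.track_frame(frames[t], cfg, init_poses=inits)
        selection = select_modes_dp(modes, cfg.smoothness_weight, pinned)
        flags = _flag_frames(modes, selection, cfg, pinned)

    estimates = []
    for t, m in enumerate(selection):
        pos, wgt = modes[t][m]
        total = sum(w for _, w in modes[t])
        conf = 1.0 if t in pinned else min(1.0, wgt / total)
        estimates.append(PoseEstimate(x=float(pos[0]), y=float(pos[1]),
                                      confidence=conf))
    shape = tuple(frames[0].shape) if frames is not None else None
    return TrackResult(estimates=estimates, flagged=flags, modes=modes,
                       image_shape=shape, pinned=pinned)


def apply_corrections(result: TrackResult, corrections: dict,
                      cfg: TrackConfig | None = None) -> TrackResult:
    """Pin manually corrected frames and re-run the smoothing around them.

    ``corrections`` maps frame index -> (x, y) px.  Corrected frames get
    confidence 1 and lose any flag; the DP re-runs with them as hard
    constraints.
    """
    cfg = cfg or TrackConfig()
    if not corrections:
        return result
    modes = [list(m) for m in result.modes]
    pinned = dict(result.pinned)
    for t, xy in corrections.items():
        if not 0 <= t < len(modes):
            raise ValueError(f"correction frame {t} out of range")
        xy = np.asarray(xy, float)
        if result.image_shape is not None:
            h, w = result.image_shape
            if not (0 <= xy[0] < w and 0 <= xy[1] < h):
                raise ValueError(f"correction for frame {t} outside image bounds")
        total = sum(w for _, w in modes[t])
        modes[t] = modes[t] + [(xy, total)]  # pinned mode, weight irrelevant
        pinned[t] = len(modes[t]) - 1
    out = smooth_track(modes, cfg, pinned=pinned)
    out.image_shape = result.image_shape
    return out


def track_to_frame(result: TrackResult):
    """Trajectory as a pandas DataFrame (frame, x_px, y_px, confidence, flagged)."""
    import pandas as pd

    flagged = set(result.flagged)
    return pd.DataFrame({
        "frame": np.arange(len(result.estimates)),
        "x_px": [e.x for e in result.estimates],
        "y_px": [e.y for e in result.estimates],
        "confidence": [e.confidence for e in result.estimates],
        "flagged": [t in flagged for t in range(len(result.estimates))],
    })
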