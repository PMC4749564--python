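"""Trajectory-level statistics comparing control, laser and rebound reaches.

Covers: inferring the pellet (Grab) and mouth (At mouth) target locations
from control trials; constructing matched control intervals for
laser-interrupted trials; distance-to-target time courses with quartile
bands and the interquartile divergence time; arc-length alignment of
trajectories; leave-one-out 1-nearest-neighbor balanced accuracy between
trial groups; Grab end-point error; and the two standard two-sample tests
(Wilcoxon-Mann-Whitney rank sum, Welch's t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ethogram import CANONICAL_EPOCHS, Trial

_CANON_INDEX = {lab: i for i, lab in enumerate(CANONICAL_EPOCHS)}


@dataclass
class TargetPositions:
    """Inferred 3D target locations (mm): pellet at Grab start, mouth at AtMouth start."""

    grab_target: np.ndarray
    mouth_target: np.ndarray
    estimator: str = "mean"

    def __post_init__(self) -> None:
        self.grab_target = np.asarray(self.grab_target, float).reshape(3)
        self.mouth_target = np.asarray(self.mouth_target, float).reshape(3)
        if not (np.all(np.isfinite(self.grab_target))
                and np.all(np.isfinite(self.mouth_target))):
            raise ValueError("targets must be finite")


def _epoch_start_position(trial: Trial, label: str) -> Optional[np.ndarray]:
    """Hand position at the first frame of the final-sequence epoch, or None."""
    chain = trial.final_prehension_sequence()
    if label not in chain or trial.trajectory3d is None:
        return None
    f = chain[label]
    if f >= len(trial.trajectory3d):
        return None
    return trial.trajectory3d[f]


def infer_targets(control_trials: Sequence[Trial],
                  estimator: str = "mean") -> TargetPositions:
    """Per-axis mean or median hand position at Grab / AtMouth starts."""
    if estimator not in ("mean", "median"):
        raise ValueError("estimator must be 'mean' or 'median'")
    grabs, mouths = [], []
    for t in control_trials:
        g = _epoch_start_position(t, "Grab")
        m = _epoch_start_position(t, "AtMouth")
        if g is not None and m is not None:
            grabs.append(g)
            mouths.append(m)
    if not grabs:
        raise ValueError("no eligible control trials with Grab and AtMouth")
    agg = np.mean if estimator == "mean" else np.median
    return TargetPositions(grab_target=agg(np.asarray(grabs), axis=0),
                           mouth_target=agg(np.asarray(mouths), axis=0),
                           estimator=estimator)


# ---------------------------------------------------------------------------
# matched-control construction


def laser_offset_frames(trial: Trial, epoch: str) -> Optional[int]:
    """Frames between the last `epoch` start preceding laser-on and laser-on."""
    if trial.laser_on is None:
        return None
    starts = [e.start for e in trial.epochs_with(epoch) if e.start <= trial.laser_on]
    if not starts:
        return None
    return trial.laser_on - starts[-1]


def exclude_uninhibited(laser_trials: Sequence[Trial], epoch: str) -> list[Trial]:
    """Drop laser trials whose Chew overlaps the laser window (no inhibition).

    Applied for interruption groups Lift through Supinate; for AtMouth and
    Chew groups a lack of effect is not detectable, so all trials are kept.
    """
    if epoch in ("AtMouth", "Chew"):
        return list(laser_trials)
    return [t for t in laser_trials if not t.chew_during_laser()]


def matched_control_intervals(control_trials: Sequence[Trial],
                              laser_trials: Sequence[Trial],
                              epoch: str,
                              seed: int = 0) -> list[tuple[Trial, int]]:
    """Control intervals matched to the laser-trial timing distribution.

    For each control trial containing the grouping epoch, draw one laser
    trial uniformly (seeded), compute its offset t = laser_on minus the
    last preceding `epoch` start, draw one qualifying epoch instance in the
    control trial uniformly, and return the interval start
    ``epoch_start + t``.  Laser trials showing no inhibition (Chew during
    the laser, for Lift..Supinate groups) are excluded first.
    """
    laser_trials = exclude_uninhibited(laser_trials, epoch)
    offsets = [laser_offset_frames(t, epoch) for t in laser_trials]
    offsets = [o for o in offsets if o is not None]
    if not offsets:
        raise ValueError(f"no usable laser trials for epoch group {epoch!r}")
    rng = np.random.default_rng(seed)
    out = []
    for c in sorted(control_trials, key=lambda t: t.trial_id):
        instances = c.epochs_with(epoch)
        if not instances:
            warnings.warn(f"control trial {c.trial_id} lacks epoch {epoch}; skipped")
            continue
        t_off = offsets[rng.integers(len(offsets))]
        inst = instances[rng.integers(len(instances))]
        out.append((c, inst.start + t_off))
    return out


# ---------------------------------------------------------------------------
# deviation time course and divergence


@dataclass
class DeviationTimecourse:
    """Quartile bands of distance-to-target (mm) versus time from laser onset."""

    times_ms: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_trials: int = 0

    def __post_init__(self) -> None:
        if np.any(self.q25 > self.median + 1e-12) or np.any(self.median > self.q75 + 1e-12):
            raise ValueError("quartile ordering violated")


def deviation_timecourse(intervals: Sequence[tuple[Trial, int]],
                         target: np.ndarray,
                         horizon_ms: float = 500.0,
                         fps: float = 500.0) -> DeviationTimecourse:
    """Distance-to-target quartile bands across trials.

    ``intervals`` pairs each trial with the frame playing the role of laser
    onset (for laser trials, ``trial.laser_on``; for controls, the matched
    interval start).  Truncates the horizon with a warning when it exceeds
    the shortest trajectory.
    """
    target = np.asarray(target, float)
    n_steps = int(round(horizon_ms * fps / 1000.0)) + 1
    avail = []
    for trial, start in intervals:
        if trial.trajectory3d is None:
            raise ValueError(f"trial {trial.trial_id} has no 3D trajectory")
        avail.append(len(trial.trajectory3d) - start)
    max_steps = min(avail)
    if max_steps < n_steps:
        warnings.warn("horizon exceeds available trajectory; truncating")
        n_steps = max(max_steps, 1)
    dists = np.empty((len(intervals), n_steps))
    for i, (trial, start) in enumerate(intervals):
        seg = trial.trajectory3d[start:start + n_steps]
        dists[i] = np.linalg.norm(seg - target, axis=1)
    times = np.arange(n_steps) * 1000.0 / fps
    return DeviationTimecourse(
        times_ms=times,
        median=np.median(dists, axis=0),
        q25=np.percentile(dists, 25, axis=0),
        q75=np.percentile(dists, 75, axis=0),
        n_trials=len(intervals),
    )


def divergence_time(a: DeviationTimecourse, b: DeviationTimecourse) -> Optional[float]:
    """First time (ms) from which the two [q25, q75] bands stay disjoint.

    Returns None if the bands never remain disjoint through the horizon.
    """
    if len(a.times_ms) != len(b.times_ms) or not np.allclose(a.times_ms, b.times_ms):
        raise ValueError("time grids do not match")
    disjoint = (a.q75 < b.q25) | (b.q75 < a.q25)
    # last index where bands overlap; divergence starts after it
    overlap_idx = np.nonzero(~disjoint)[0]
    if len(overlap_idx) == 0:
        return float(a.times_ms[0])
    last = overlap_idx[-1]
    if last + 1 >= len(a.times_ms):
        return None
    return float(a.times_ms[last + 1])


# ---------------------------------------------------------------------------
# arc-length alignment and nearest-neighbor comparison

DEFAULT_CHECKPOINTS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass
class AlignedTrajectory:
    """Positions sampled at fixed arc-length fractions of a reach."""

    checkpoints: np.ndarray  # fractions in [0, 1], strictly increasing
    positions: np.ndarray    # (n_checkpoints, 3) mm

    def __post_init__(self) -> None:
        self.checkpoints = np.asarray(self.checkpoints, float)
        self.positions = np.asarray(self.positions, float)
        if np.any(np.diff(self.checkpoints) <= 0):
            raise ValueError("checkpoint fractions must be strictly increasing")
        if not (np.isclose(self.checkpoints[0], 0.0)
                and np.isclose(self.checkpoints[-1], 1.0)):
            raise ValueError("checkpoints must span [0, 1]")


def align_by_arclength(segment: np.ndarray,
                       checkpoints=DEFAULT_CHECKPOINTS) -> AlignedTrajectory:
    """Align a trajectory segment by relative distance traveled.

    The cumulative arc length is normalized to [0, 1] and positions are
    linearly interpolated at the checkpoint fractions; the result is
    invariant to time reparameterization of the segment.
    """
    seg = np.asarray(segment, float)
    if seg.ndim != 2 or len(seg) < 2:
        raise ValueError("segment must be an (n>=2, d) array")
    steps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    total = steps.sum()
    if total <= 0:
        raise ValueError("zero total path length")
    s = np.concatenate([[0.0], np.cumsum(steps)]) / total
    # collapse zero-length runs so s is strictly increasing for interp
    keep = np.concatenate([[True], np.diff(s) > 0])
    s, seg = s[keep], seg[keep]
    cps = np.asarray(checkpoints, float)
    pos = np.column_stack([np.interp(cps, s, seg[:, d]) for d in range(seg.shape[1])])
    return AlignedTrajectory(checkpoints=cps, positions=pos)


def reach_segment(trial: Trial) -> Optional[np.ndarray]:
    """Trajectory from the final-sequence Lift start to the Grab start."""
    chain = trial.final_prehension_sequence()
    if "Lift" not in chain or "Grab" not in chain or trial.trajectory3d is None:
        return None
    lo, hi = chain["Lift"], chain["Grab"]
    if hi <= lo + 1 or hi >= len(trial.trajectory3d):
        return None
    return trial.trajectory3d[lo:hi + 1]


def nn_balanced_accuracy(group_a: Sequence[AlignedTrajectory],
                         group_b: Sequence[AlignedTrajectory],
                         checkpoint: int | float = -1) -> float:
    """Leave-one-out 1-NN balanced accuracy between two trajectory groups.

    ``checkpoint`` selects the aligned position compared: an integer index
    into the checkpoint list, or a float fraction matched against the
    checkpoint values.  0.5 is chance regardless of group sizes; 1.0 is
    perfect separation.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 trials")

    def pick(tr: AlignedTrajectory) -> np.ndarray:
        if isinstance(checkpoint, (int, np.integer)):
            return tr.positions[checkpoint]
        idx = np.argmin(np.abs(tr.checkpoints - checkpoint))
        return tr.positions[idx]

    pts = np.array([pick(t) for t in list(group_a) + list(group_b)])
    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    pred = labels[d2.argmin(axis=1)]
    tpr = np.mean(pred[labels == 0] == 0)
    tnr = np.mean(pred[labels == 1] == 1)
    return float((tpr + tnr) / 2.0)


# ---------------------------------------------------------------------------
# end-point error


def grab_error(trials: Sequence[Trial],
               reference_trials: Sequence[Trial]) -> tuple[np.ndarray, dict]:
    """Distance of each trial's Grab position to the reference median Grab.

    The reference is the per-axis median Grab-start position over control
    success trials.  Returns per-trial distances (mm, NaN where no Grab)
    and a summary with the median and median absolute deviation.
    """
    ref = [p for p in (_epoch_start_position(t, "Grab") for t in reference_trials)
           if p is not None]
    if not ref:
        raise ValueError("empty reference: no control trials with a Grab position")
    ref_med = np.median(np.asarray(ref), axis=0)
    dists = np.full(len(trials), np.nan)
    for i, t in enumerate(trials):
        p = _epoch_start_position(t, "Grab")
        if p is not None:
            dists[i] = np.linalg.norm(p - ref_med)
    valid = dists[np.isfinite(dists)]
    summary = {
        "n": int(len(valid)),
        "median_mm": float(np.median(valid)) if len(valid) else np.nan,
        "mad_mm": float(np.median(np.abs(valid - np.median(valid)))) if len(valid) else np.nan,
    }
    return dists, summary


# ---------------------------------------------------------------------------
# two-sample tests


def compare_distributions(sample_a, sample_b,
                          method: str = "rank_sum") -> tuple[float, float]:
    """Two-sided two-sample test: Wilcoxon-Mann-Whitney or Welch's t.

    The rank-sum test uses the exact null distribution when the pooled
    sample size is at most 20 and there are no ties, and the normal
    approximation with tie correction otherwise.  All-identical pooled
    values give p = 1 with a warning.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        warnings.warn("degenerate samples (all values identical); p = 1")
        return 0.0, 1.0
    if method == "rank_sum":
        has_ties = len(np.unique(pooled)) < len(pooled)
        exact = (len(pooled) <= 20) and not has_ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'rank_sum' or 'welch_t'")


def compare_dispersion(sample_a, sample_b) -> tuple[float, float]:
    """Rank-based two-sample dispersion test (Fligner-Killeen).

    Tests equality of spread without assuming equal location (each sample
    is centered on its own median), which is the appropriate rank-based
    companion to the rank-sum location test when latency variances are
    compared between conditions with different medians.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    res = stats.fligner(a, b)
    return float(res.statistic), float(res.pvalue)


def nn_accuracy_profile(group_a: Sequence[AlignedTrajectory],
                        group_b: Sequence[AlignedTrajectory],
                        checkpoints=DEFAULT_CHECKPOINTS) -> dict:
    """Balanced 1-NN accuracy at each checkpoint plus their mean.

    The per-checkpoint values correspond to asking, at a given fraction of
    distance traveled, how separable the two groups' hand positions are;
    the mean over the standard checkpoints summarizes the classifier for
    the whole reach.
    """
    per = {float(cp): nn_balanced_accuracy(group_a, group_b, float(cp))
           for cp in checkpoints}
    return {"per_checkpoint": per, "mean": float(np.mean(list(per.values())))}


def holm_correction(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiple-testing control)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
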