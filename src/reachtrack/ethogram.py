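"""Trial data model and ethogram statistics for cued-prehension sessions.

A trial is a timeline of labeled behavioral epochs (Lift, Hand open, Grab,
Supinate, At mouth, Chew, ...) plus events: the auditory cue, an optional
optogenetic laser window, and pellet presence.  Times are stored as frame
indices (0-based, half-open intervals ``[start, end)``) and converted to
milliseconds at the trial's frame rate only in reports.

Statistics implemented here: trial validation against the canonical epoch
ordering, latency/interval measures referenced to the cue (control trials)
or to laser offset (rebound trials), initiation rates over a bracketed
window, cumulative First-Lift histograms, and epoch-progression histograms
with count-matched control subsampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical order of the prehension components.
CANONICAL_EPOCHS = ("Lift", "HandOpen", "Grab", "Supinate", "AtMouth", "Chew")

#: All recognized epoch labels (canonical plus non-prehension behaviors).
EPOCH_LABELS = CANONICAL_EPOCHS + ("ChewNoPellet", "Lick", "Groom")

_CANON_INDEX = {lab: i for i, lab in enumerate(CANONICAL_EPOCHS)}

OUTCOMES = ("success", "failure", "no_initiation")


@dataclass
class EpochInterval:
    """A labeled behavioral epoch over the half-open frame interval [start, end)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")
        if not self.start < self.end:
            raise ValueError(f"epoch {self.label}: start {self.start} must be < end {self.end}")


@dataclass
class Trial:
    """One behavioral trial: events, epoch annotations, optional 3D trajectory."""

    trial_id: str
    animal_id: str = "animal0"
    cue: Optional[int] = None
    laser_on: Optional[int] = None
    laser_off: Optional[int] = None
    pellet_present: bool = True
    epochs: list[EpochInterval] = field(default_factory=list)
    outcome: str = "success"
    trajectory3d: Optional[np.ndarray] = None  # (n_frames, 3) mm, world frame
    fps: float = 500.0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.trajectory3d is not None:
            self.trajectory3d = np.asarray(self.trajectory3d, dtype=float)

    # -- epoch queries -------------------------------------------------

    def epochs_with(self, label: str) -> list[EpochInterval]:
        return sorted((e for e in self.epochs if e.label == label), key=lambda e: e.start)

    def has_epoch(self, label: str) -> bool:
        return any(e.label == label for e in self.epochs)

    def first_lift_after(self, frame: int) -> Optional[int]:
        lifts = [e.start for e in self.epochs if e.label == "Lift" and e.start >= frame]
        return min(lifts) if lifts else None

    def epoch_at_laser_onset(self) -> Optional[str]:
        """Last canonical component initiated at or before laser onset."""
        if self.laser_on is None:
            return None
        started = [e for e in self.epochs
                   if e.label in _CANON_INDEX and e.start <= self.laser_on]
        if not started:
            return None
        return max(started, key=lambda e: (e.start, _CANON_INDEX[e.label])).label

    def chew_during_laser(self) -> bool:
        if self.laser_on is None or self.laser_off is None:
            return False
        return any(e.label == "Chew" and e.start < self.laser_off and e.end > self.laser_on
                   for e in self.epochs)

    def final_prehension_sequence(self) -> dict[str, int]:
        """First frames of the last maximal canonical epoch chain.

        Starting from the last Lift, greedily picks for each canonical label
        the first interval of that label starting at or after the previously
        selected start.  Returns a map label -> first frame for the labels
        that chain together.
        """
        lifts = self.epochs_with("Lift")
        if not lifts:
            return {}
        chain = {"Lift": lifts[-1].start}
        t = lifts[-1].start
        for label in CANONICAL_EPOCHS[1:]:
            cands = [e.start for e in self.epochs_with(label) if e.start >= t]
            if not cands:
                continue
            chain[label] = cands[0]
            t = cands[0]
        return chain


def validate_trial(trial: Trial) -> list[str]:
    """Check a trial against the annotation invariants.

    Returns an empty list iff the trial is valid; otherwise a list of
    human-readable violation descriptions, each naming the rule breached.
    """
    violations: list[str] = []
    for e in trial.epochs:
        if not e.start < e.end:  # unreachable via constructor, but data may be loaded
            violations.append(f"interval: epoch {e.label} has start >= end")
    if trial.laser_on is not None and trial.laser_off is not None:
        if not trial.laser_on < trial.laser_off:
            violations.append("laser: laser_on must precede laser_off")
    if (trial.laser_on is None) != (trial.laser_off is None):
        violations.append("laser: laser_on and laser_off must both be present or absent")

    canonical_present = {e.label for e in trial.epochs if e.label in _CANON_INDEX}
    if trial.outcome == "no_initiation" and "Lift" in canonical_present:
        violations.append("outcome: no_initiation trial contains a Lift")
    if canonical_present:
        if "Lift" not in canonical_present:
            missing_ok = canonical_present <= {"Chew"}  # chewing alone is permitted
            if not missing_ok:
                violations.append("ordering: canonical epochs present without any Lift")
        else:
            chain = trial.final_prehension_sequence()
            unreachable = canonical_present - set(chain)
            for label in sorted(unreachable, key=_CANON_INDEX.get):
                violations.append(
                    f"ordering: epoch {label} cannot be placed after the preceding "
                    "canonical components (canonical order Lift < HandOpen < Grab "
                    "< Supinate < AtMouth < Chew on first frames)")
    return violations


@dataclass
class IntervalStats:
    """Latency and inter-component intervals in milliseconds.

    ``first_lift`` is referenced to the cue (control) or to laser offset
    (rebound); the pairwise intervals are differences of first frames, the
    Grab/Supinate/AtMouth ones within the final prehension sequence.
    Undefined intervals are ``None``.
    """

    first_lift: Optional[float] = None
    lift_to_handopen: Optional[float] = None
    lift_to_grab: Optional[float] = None
    handopen_to_grab: Optional[float] = None
    grab_to_supinate: Optional[float] = None
    supinate_to_atmouth: Optional[float] = None
    grab_to_atmouth: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def interval_stats(trial: Trial, reference: str = "cue") -> IntervalStats:
    """Compute latency statistics referenced to the cue or to laser offset.

    ``reference`` selects the zero time: ``"cue"`` for control trials or
    ``"laser_off"`` for rebound trials.  Raises ``ValueError`` when the
    reference event is absent.
    """
    if reference == "cue":
        ref = trial.cue
    elif reference == "laser_off":
        ref = trial.laser_off
    else:
        raise ValueError(f"reference must be 'cue' or 'laser_off', got {reference!r}")
    if ref is None:
        raise ValueError(f"reference event {reference!r} is absent from trial {trial.trial_id}")

    ms = 1000.0 / trial.fps
    out = IntervalStats()
    first_lift = trial.first_lift_after(ref)
    if first_lift is None:
        return out
    out.first_lift = (first_lift - ref) * ms

    def first_start(label: str, after: int) -> Optional[int]:
        cands = [e.start for e in trial.epochs_with(label) if e.start >= after]
        return cands[0] if cands else None

    handopen = first_start("HandOpen", first_lift)
    grab = first_start("Grab", first_lift)
    if handopen is not None:
        out.lift_to_handopen = (handopen - first_lift) * ms
        if grab is not None and grab >= handopen:
            out.handopen_to_grab = (grab - handopen) * ms
    if grab is not None:
        out.lift_to_grab = (grab - first_lift) * ms

    chain = trial.final_prehension_sequence()
    if "Grab" in chain and "Supinate" in chain:
        out.grab_to_supinate = (chain["Supinate"] - chain["Grab"]) * ms
    if "Supinate" in chain and "AtMouth" in chain:
        out.supinate_to_atmouth = (chain["AtMouth"] - chain["Supinate"]) * ms
    if "Grab" in chain and "AtMouth" in chain:
        out.grab_to_atmouth = (chain["AtMouth"] - chain["Grab"]) * ms
    return out


def initiation_rate(trials: Sequence[Trial],
                    window: tuple[int, int],
                    reference: str = "cue") -> tuple[int, int]:
    """Count trials with a Lift starting inside a bracketed window.

    The window is in frames relative to the reference event (cue or
    laser_off), half-open ``[lo, hi)``.  Trials lacking the reference event
    count toward the total but cannot initiate.  Returns exact integer
    counts ``(initiated, total)``.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must be ordered (lo < hi)")
    initiated = 0
    for t in trials:
        ref = t.cue if reference == "cue" else t.laser_off
        if ref is None:
            continue
        if any(e.label == "Lift" and lo <= e.start - ref < hi for e in t.epochs):
            initiated += 1
    return initiated, len(trials)


@dataclass
class StepFunction:
    """Monotone step function time (ms) -> cumulative count."""

    times_ms: np.ndarray   # sorted step locations
    counts: np.ndarray     # value from each step location onward

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times_ms, np.asarray(t, float), side="right") - 1
        vals = np.concatenate([[0], self.counts])
        return vals[idx + 1]

    @property
    def terminal(self) -> int:
        return int(self.counts[-1]) if len(self.counts) else 0


def cumulative_first_lift(trials: Sequence[Trial],
                          reference: str = "cue",
                          window: Optional[tuple[int, int]] = None) -> StepFunction:
    """Running total over trials of First-Lift occurrence versus latency.

    Latencies are in ms relative to the reference event.  Non-initiating
    trials contribute nothing; the terminal value equals the number of
    initiating trials (and matches :func:`initiation_rate` on the same
    window).
    """
    latencies = []
    for t in trials:
        ref = t.cue if reference == "cue" else t.laser_off
        if ref is None:
            continue
        if window is not None:
            lo, hi = window
            lifts = [e.start for e in t.epochs
                     if e.label == "Lift" and lo <= e.start - ref < hi]
            first = min(lifts) if lifts else None
        else:
            first = t.first_lift_after(ref)
        if first is not None:
            latencies.append((first - ref) * 1000.0 / t.fps)
    if not latencies:
        return StepFunction(times_ms=np.array([]), counts=np.array([], dtype=int))
    times = np.sort(np.asarray(latencies, float))
    uniq, cnt = np.unique(times, return_counts=True)
    return StepFunction(times_ms=uniq, counts=np.cumsum(cnt))


def _achieves(trial: Trial, label: str) -> bool:
    return trial.has_epoch(label)


def progression_histogram(laser_trials: Sequence[Trial],
                          control_trials: Sequence[Trial],
                          seed: int = 0,
                          exclude_uninhibited: bool = True) -> pd.DataFrame:
    """Per-transition success percentages for laser vs matched control trials.

    Laser trials are grouped by the epoch ongoing at laser onset (the last
    canonical component initiated before the laser).  For each group, an
    equal number of control trials is drawn per animal with a seeded RNG,
    restricted to control trials that achieved at least the grouping epoch.
    For each canonical transition at or beyond the grouping epoch, the
    percentage of trials containing the later epoch (starting after the
    grouping-epoch start) is reported for both conditions.

    For groups Lift..Supinate, laser trials whose Chew epoch overlaps the
    laser window (prehension evidently not inhibited) are excluded first;
    AtMouth/Chew groups keep all trials.

    Returns a tidy DataFrame with columns
    ``group, transition, condition, n, n_success, percent``.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[Trial]] = {}
    for t in sorted(laser_trials, key=lambda t: t.trial_id):
        g = t.epoch_at_laser_onset()
        if g is None:
            continue
        if exclude_uninhibited and _CANON_INDEX[g] <= _CANON_INDEX["Supinate"] \
                and t.chew_during_laser():
            continue
        groups.setdefault(g, []).append(t)

    rows = []
    for g in sorted(groups, key=_CANON_INDEX.get):
        gl = groups[g]
        gi = _CANON_INDEX[g]
        # matched controls per animal
        matched: list[Trial] = []
        laser_by_animal: dict[str, int] = {}
        for t in gl:
            laser_by_animal[t.animal_id] = laser_by_animal.get(t.animal_id, 0) + 1
        for animal, k in sorted(laser_by_animal.items()):
            eligible = sorted((c for c in control_trials
                               if c.animal_id == animal and _achieves(c, g)),
                              key=lambda c: c.trial_id)
            if not eligible:
                raise ValueError(
                    f"no eligible control trials for group {g!r}, animal {animal!r}")
            replace = len(eligible) < k
            if replace:
                warnings.warn(f"group {g!r}, animal {animal!r}: only {len(eligible)} "
                              f"controls for {k} laser trials; sampling with replacement")
            idx = rng.choice(len(eligible), size=k, replace=replace)
            matched.extend(eligible[i] for i in idx)

        transitions = [(CANONICAL_EPOCHS[i], CANONICAL_EPOCHS[i + 1])
                       for i in range(gi, len(CANONICAL_EPOCHS) - 1)]
        for frm, to in transitions:
            for cond, trset in (("laser", gl), ("control", matched)):
                n_succ = 0
                for t in trset:
                    starts = [e.start for e in t.epochs_with(g)]
                    if cond == "laser":
                        # the instance ongoing at laser onset anchors progression
                        starts = [s for s in starts if s <= t.laser_on]
                    if not starts:
                        continue
                    anchor = starts[-1]
                    if any(e.label == to and e.start > anchor for e in t.epochs):
                        n_succ += 1
                rows.append({
                    "group": g, "transition": f"{frm}->{to}", "condition": cond,
                    "n": len(trset), "n_success": n_succ,
                    "percent": 100.0 * n_succ / len(trset) if trset else np.nan,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization


def _trial_to_dict(t: Trial) -> dict:
    return {
        "trial_id": t.trial_id, "animal_id": t.animal_id,
        "cue": t.cue, "laser_on": t.laser_on, "laser_off": t.laser_off,
        "pellet_present": bool(t.pellet_present),
        "outcome": t.outcome,
        "epochs": [{"label": e.label, "start": int(e.start), "end": int(e.end)}
                   for e in t.epochs],
        "has_trajectory": t.trajectory3d is not None,
    }


def save_session(trials: Sequence[Trial], path, fps: float = 500.0,
                 animal_id: Optional[str] = None) -> None:
    """Write a session of trials to a JSON file (trajectories go to CSV separately)."""
    doc = {
        "fps": fps,
        "animal_id": animal_id or (trials[0].animal_id if trials else None),
        "trials": [_trial_to_dict(t) for t in trials],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_session(path, trajectories: Optional[dict] = None) -> list[Trial]:
    """Load a session JSON; ``trajectories`` optionally maps trial_id -> (n,3) array."""
    with open(path) as fh:
        doc = json.load(fh)
    fps = doc.get("fps", 500.0)
    out = []
    for d in doc["trials"]:
        traj = (trajectories or {}).get(d["trial_id"])
        out.append(Trial(
            trial_id=d["trial_id"], animal_id=d["animal_id"],
            cue=d["cue"], laser_on=d["laser_on"], laser_off=d["laser_off"],
            pellet_present=d["pellet_present"], outcome=d["outcome"],
            epochs=[EpochInterval(**e) for e in d["epochs"]],
            trajectory3d=traj, fps=fps,
        ))
    return out


def epochs_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Flat epoch table: one row per epoch interval."""
    rows = [{"trial_id": t.trial_id, "animal_id": t.animal_id,
             "label": e.label, "start": e.start, "end": e.end}
            for t in trials for e in t.epochs]
    return pd.DataFrame(rows, columns=["trial_id", "animal_id", "label", "start", "end"])


def epochs_from_frame(df: pd.DataFrame, fps: float = 500.0) -> list[Trial]:
    """Rebuild bare trials (epochs only) from a flat epoch table.

    The inverse of :func:`epochs_to_frame` up to events and trajectories,
    which the flat format does not carry.
    """
    out = []
    for (tid, animal), g in df.groupby(["trial_id", "animal_id"], sort=False):
        epochs = [EpochInterval(label=r.label, start=int(r.start), end=int(r.end))
                  for r in g.itertuples()]
        out.append(Trial(trial_id=str(tid), animal_id=str(animal), cue=None,
                         epochs=epochs, fps=fps))
    return out
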