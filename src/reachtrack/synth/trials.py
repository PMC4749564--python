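"""Simulation of single prehension trials and whole sessions.

A cued trial rests at the perch, initiates a reach after a Gaussian
First-Lift latency, travels perch -> pellet -> mouth along minimum-jerk
segments, and ends chewing.  Epochs are laid out consecutively in the
canonical order Lift -> HandOpen -> Grab -> Supinate -> AtMouth -> Chew,
with log-normal durations.  The hand is at the pellet throughout Grab and
reaches the mouth at the AtMouth start, so the Grab-start hand position
recovers the pellet location up to the position noise.

An optogenetic laser window perturbs the trial: movement not yet started is
withheld for the laser's duration; movement in progress freezes after a
short uniform latency (velocity decays exponentially over ~30 ms); chewing
is unaffected.  After laser offset a rebound reach is generated with a
probability that grows with laser duration, after a Normal latency that is
typically shorter and less variable than the cued latency.
"""

from __future__ import annotations

import numpy as np

from ..ethogram import CANONICAL_EPOCHS, EpochInterval, Trial
from .params import PerturbationParams, ReachKinematicsParams

#: exponential time constant of the freezing velocity decay, ms; the decay
#: is effectively complete (five time constants) within 30 ms
FREEZE_DECAY_TAU_MS = 6.0


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]: 10 t^3 - 15 t^4 + 6 t^5."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _ms_to_frames(ms: float, fps: float) -> int:
    return max(1, int(round(ms * fps / 1000.0)))


def _draw_durations(rng: np.random.Generator, kin: ReachKinematicsParams) -> dict:
    """Log-normal epoch durations (frames) with the configured mean and CV."""
    out = {}
    cv = kin.epoch_duration_cv
    sigma2 = np.log1p(cv * cv)
    for label in CANONICAL_EPOCHS:
        mean = kin.epoch_duration_means[label]
        if cv > 0:
            mu = np.log(mean) - sigma2 / 2.0
            d = float(rng.lognormal(mu, np.sqrt(sigma2)))
        else:
            d = mean
        out[label] = _ms_to_frames(d, kin.fps)
    return out


def _reach_plan(start_frame: int, durations: dict, start_pos, pellet, mouth,
                include_chew: bool = True):
    """Epoch starts and minimum-jerk segments for one reach from start_pos.

    Returns (epochs, segments); segments are (t0, t1, p0, p1) tuples and the
    hand holds its position between segments.
    """
    starts = {}
    t = start_frame
    labels = list(CANONICAL_EPOCHS if include_chew else CANONICAL_EPOCHS[:-1])
    for label in labels:
        starts[label] = t
        t += durations[label]
    end = t
    epochs = []
    order = labels
    for i, label in enumerate(order):
        e_end = starts[order[i + 1]] if i + 1 < len(order) else end
        epochs.append(EpochInterval(label=label, start=starts[label], end=e_end))
    segments = [
        (starts["Lift"], starts["Grab"], np.asarray(start_pos, float), np.asarray(pellet, float)),
        (starts["Supinate"], starts["AtMouth"], np.asarray(pellet, float), np.asarray(mouth, float)),
    ]
    return epochs, segments


def _fill_segments(traj: np.ndarray, rest_pos, segments) -> None:
    """Paint minimum-jerk segments (holding position in between) onto traj."""
    n = len(traj)
    cursor = 0
    current = np.asarray(rest_pos, float)
    for (t0, t1, p0, p1) in segments:
        t0c, t1c = max(0, min(t0, n)), max(0, min(t1, n))
        if t0c > cursor:
            traj[cursor:t0c] = current
        if t1c > t0c:
            tau = (np.arange(t0c, t1c) - t0) / max(t1 - t0, 1)
            s = minimum_jerk(tau)
            traj[t0c:t1c] = p0 + np.outer(s, p1 - p0)
        current = p1
        cursor = max(cursor, t1c)
    if cursor < n:
        traj[cursor:] = current


def _clip_epochs(epochs, n_frames: int):
    out = []
    for e in epochs:
        if e.start >= n_frames:
            continue
        out.append(EpochInterval(e.label, e.start, min(e.end, n_frames)))
    return out


def simulate_trial(kin: ReachKinematicsParams,
                   pert: PerturbationParams | None = None,
                   seed: int = 0,
                   *,
                   trial_id: str = "trial0",
                   animal_id: str = "animal0",
                   cued: bool = True,
                   cue_frame: int = 250,
                   n_frames: int = 3000,
                   pellet_present: bool = True,
                   laser_align_epoch: str | None = None,
                   laser_align_offset_ms: float = 20.0) -> Trial:
    """Simulate one trial; ``pert=None`` gives an unperturbed cued trial.

    ``laser_align_epoch`` repositions the laser onset a fixed offset after
    the start of the named epoch of the planned reach (useful for building
    laser-during-Lift / -Grab / ... groups); otherwise ``pert.laser_on`` is
    an absolute frame.  Raises ``ValueError`` if the laser window does not
    fit inside the trial.
    """
    rng = np.random.default_rng(seed)
    fps = kin.fps
    traj = np.empty((n_frames, 3), float)

    # planned (unperturbed) reach
    durations = _draw_durations(rng, kin)
    # truncated Gaussian: physiological floor at 50 ms, clamp at +4 SD
    latency_ms = float(np.clip(
        rng.normal(kin.first_lift_latency_mean_control,
                   kin.first_lift_latency_sd_control),
        50.0,
        kin.first_lift_latency_mean_control + 4 * kin.first_lift_latency_sd_control))
    lift_start = (cue_frame + _ms_to_frames(latency_ms, fps)) if cued else None

    epochs: list[EpochInterval] = []
    outcome = "success"
    laser_on = laser_off = None

    if cued:
        plan_epochs, plan_segments = _reach_plan(
            lift_start, durations, kin.perch_pos, kin.pellet_pos, kin.mouth_pos,
            include_chew=pellet_present)
    else:
        plan_epochs, plan_segments = [], []

    if pert is None:
        _fill_segments(traj, kin.perch_pos, plan_segments)
        epochs = plan_epochs
        if not cued:
            outcome = "no_initiation"
    else:
        laser_on = int(pert.laser_on)
        if laser_align_epoch is not None:
            if not cued:
                raise ValueError("laser_align_epoch requires a cued trial")
            anchor = next(e.start for e in plan_epochs if e.label == laser_align_epoch)
            laser_on = anchor + _ms_to_frames(laser_align_offset_ms, fps)
        laser_off = laser_on + _ms_to_frames(pert.laser_duration, fps)
        if laser_on < 0 or laser_off > n_frames:
            raise ValueError("laser window outside trial duration")

        p_rebound = pert.rebound_probability()
        do_rebound = bool(rng.random() < p_rebound)
        rebound_latency_ms = max(2.0, rng.normal(pert.rebound_latency_mean,
                                                 pert.rebound_latency_sd))
        freeze_latency_ms = float(rng.uniform(*pert.freeze_latency_range))
        do_retract = bool(rng.random() < pert.retraction_probability)
        rebound_durations = _draw_durations(rng, kin)

        chew_start = next((e.start for e in plan_epochs if e.label == "Chew"), None)

        if cued and lift_start < laser_on and (chew_start is None or laser_on < chew_start):
            # laser strikes mid-movement: freeze after a short latency
            base = np.empty_like(traj)
            _fill_segments(base, kin.perch_pos, plan_segments)
            # the drawn latency is the observable time-to-frozen: the ~30 ms
            # velocity decay completes at laser_on + latency
            decay_start_ms = max(0.0, freeze_latency_ms - 5.0 * FREEZE_DECAY_TAU_MS)
            freeze_frame = min(laser_on + max(1, int(round(decay_start_ms * fps / 1000.0))),
                               n_frames - 1)
            tau_frames = FREEZE_DECAY_TAU_MS * fps / 1000.0
            traj[:freeze_frame + 1] = base[:freeze_frame + 1]
            pos = base[freeze_frame].copy()
            for t in range(freeze_frame + 1, min(laser_off, n_frames)):
                step = (base[t] - base[t - 1]) * np.exp(-(t - 1 - freeze_frame) / tau_frames)
                pos = pos + step
                traj[t] = pos
            frozen_end = min(laser_off, n_frames)
            epochs = [EpochInterval(e.label, e.start, min(e.end, freeze_frame + 1))
                      for e in plan_epochs if e.start <= freeze_frame]
            if do_retract and frozen_end - freeze_frame > _ms_to_frames(300, fps):
                # drift to a characteristic mid-air point during prolonged laser
                retract_point = (kin.perch_pos + kin.pellet_pos) / 2 + np.array([0, 0, 3.0])
                r0 = min(freeze_frame + _ms_to_frames(50, fps), frozen_end - 1)
                r1 = min(r0 + _ms_to_frames(200, fps), frozen_end)
                tail = np.empty((n_frames - r0, 3), float)
                _fill_segments(tail, traj[r0].copy(),
                               [(0, r1 - r0, traj[r0].copy(), retract_point)])
                traj[r0:] = tail
                hold_from = r1
                hold_pos = retract_point
            else:
                hold_from = frozen_end
                hold_pos = traj[frozen_end - 1].copy()
                traj[hold_from:] = hold_pos
            outcome = "failure"
            if do_rebound and laser_off < n_frames:
                rb_lift = laser_off + _ms_to_frames(rebound_latency_ms, fps)
                rb_epochs, rb_segments = _reach_plan(
                    rb_lift, rebound_durations, hold_pos,
                    kin.pellet_pos + pert.rebound_offset_mm, kin.mouth_pos,
                    include_chew=pellet_present)
                rb_clipped = _clip_epochs(rb_epochs, n_frames)
                epochs.extend(rb_clipped)
                if any(e.label == "AtMouth" for e in rb_clipped):
                    outcome = "success" if pellet_present else "failure"
                tail = np.empty((n_frames - hold_from, 3), float)
                shifted = [(t0 - hold_from, t1 - hold_from, p0, p1)
                           for (t0, t1, p0, p1) in rb_segments]
                _fill_segments(tail, hold_pos, shifted)
                traj[hold_from:] = tail
        elif cued and chew_start is not None and laser_on >= chew_start:
            # laser entirely during chewing: movement unaffected
            _fill_segments(traj, kin.perch_pos, plan_segments)
            epochs = plan_epochs
        else:
            # laser covers the cue / pre-movement period: initiation withheld
            rest = kin.perch_pos
            outcome = "no_initiation"
            epochs = []
            if do_rebound and laser_off < n_frames:
                rb_lift = laser_off + _ms_to_frames(rebound_latency_ms, fps)
                rb_epochs, rb_segments = _reach_plan(
                    rb_lift, rebound_durations, rest,
                    kin.pellet_pos + pert.rebound_offset_mm, kin.mouth_pos,
                    include_chew=pellet_present)
                _fill_segments(traj, rest, rb_segments)
                epochs = _clip_epochs(rb_epochs, n_frames)
                if any(e.label == "AtMouth" for e in epochs):
                    outcome = "success" if pellet_present else "failure"
                else:
                    outcome = "failure"
            else:
                traj[:] = rest

    if kin.position_noise_sd > 0:
        traj = traj + rng.normal(0.0, kin.position_noise_sd, size=traj.shape)

    epochs = _clip_epochs(epochs, n_frames)
    if not any(e.label == "Lift" for e in epochs):
        outcome = "no_initiation"
    return Trial(
        trial_id=trial_id, animal_id=animal_id,
        cue=cue_frame if cued else None,
        laser_on=laser_on, laser_off=laser_off,
        pellet_present=pellet_present,
        epochs=epochs, outcome=outcome,
        trajectory3d=traj, fps=fps,
    )


def simulate_control_session(kin: ReachKinematicsParams, n_trials: int,
                             seed: int = 0, animal_id: str = "animal0",
                             n_frames: int = 3000) -> list[Trial]:
    """Unperturbed cued trials."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_trials)
    return [simulate_trial(kin, None, int(s) % (2 ** 31),
                           trial_id=f"{animal_id}-ctl{i:04d}", animal_id=animal_id,
                           n_frames=n_frames)
            for i, s in enumerate(seeds)]


def simulate_rebound_session(kin: ReachKinematicsParams, pert: PerturbationParams,
                             n_trials: int, seed: int = 0,
                             animal_id: str = "animal0",
                             cued: bool = False, pellet_present: bool = False,
                             n_frames: int = 3000) -> list[Trial]:
    """Laser trials in the no-cue/no-pellet configuration (rebound elicitation)."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_trials)
    return [simulate_trial(kin, pert, int(s) % (2 ** 31),
                           trial_id=f"{animal_id}-rb{i:04d}", animal_id=animal_id,
                           cued=cued, pellet_present=pellet_present, n_frames=n_frames)
            for i, s in enumerate(seeds)]


def simulate_perturbed_session(kin: ReachKinematicsParams, pert: PerturbationParams,
                               n_trials: int, seed: int = 0,
                               animal_id: str = "animal0",
                               laser_align_epoch: str | None = "Lift",
                               n_frames: int = 3000) -> list[Trial]:
    """Cued trials with the laser aligned to an epoch of the planned reach."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_trials)
    return [simulate_trial(kin, pert, int(s) % (2 ** 31),
                           trial_id=f"{animal_id}-las{i:04d}", animal_id=animal_id,
                           laser_align_epoch=laser_align_epoch, n_frames=n_frames)
            for i, s in enumerate(seeds)]


def simulate_session(kin: ReachKinematicsParams,
                     pert: PerturbationParams,
                     n_trials: int,
                     laser_fraction: float = 0.2,
                     seed: int = 0,
                     animal_id: str = "animal0",
                     laser_align_epoch: str | None = "Lift",
                     n_frames: int = 3000) -> list[Trial]:
    """Mixed session: control trials with randomly interspersed laser trials."""
    rng = np.random.default_rng(seed)
    is_laser = rng.random(n_trials) < laser_fraction
    ss = np.random.SeedSequence(seed + 1)
    seeds = ss.generate_state(n_trials)
    out = []
    for i, (las, s) in enumerate(zip(is_laser, seeds)):
        if las:
            t = simulate_trial(kin, pert, int(s) % (2 ** 31),
                               trial_id=f"{animal_id}-t{i:04d}", animal_id=animal_id,
                               laser_align_epoch=laser_align_epoch, n_frames=n_frames)
        else:
            t = simulate_trial(kin, None, int(s) % (2 ** 31),
                               trial_id=f"{animal_id}-t{i:04d}", animal_id=animal_id,
                               n_frames=n_frames)
        out.append(t)
    return out
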