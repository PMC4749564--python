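"""End-to-end orchestration: synth -> track -> reconstruct -> analyze -> report.

Each stage reads the previous stage's files from the run directory and
writes its own, so stages can be re-run or substituted (e.g. tracking can
be skipped when ground-truth 2D tracks are supplied).  A manifest records
the configuration hash and a checksum for every output file; identical
configurations and seeds reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .ethogram import (cumulative_first_lift, initiation_rate, interval_stats,
                       load_session, progression_histogram, save_session)
from .ephys import psth, rebound_modulation
from .kinematics import (align_by_arclength, compare_distributions,
                         deviation_timecourse, divergence_time, grab_error,
                         infer_targets, matched_control_intervals,
                         nn_balanced_accuracy, reach_segment)
from .stereo import StereoRig, default_rig, triangulate_track
from .synth import (PerturbationParams, ReachKinematicsParams, SceneParams,
                    SpikeSimParams, read_frame_stack, render_stereo_video,
                    simulate_rebound_session, simulate_session, simulate_trial,
                    simulate_spike_trains, write_video)
from .tracker import CascadeTracker, TrackConfig, track_to_frame

log = logging.getLogger("reachtrack")


class StageError(RuntimeError):
    """A stage is missing its upstream inputs."""


@dataclass
class RunManifest:
    """Provenance of a pipeline run."""

    config_hash: str
    version: str = __version__
    files: dict = field(default_factory=dict)   # relpath -> sha256
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "version": self.version,
                       "files": dict(sorted(self.files.items())),
                       "warnings": self.warnings}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config_hash=d["config_hash"], version=d["version"],
                   files=d["files"], warnings=d["warnings"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _kin_from_config(cfg: RunConfig) -> ReachKinematicsParams:
    s = cfg.synth
    return ReachKinematicsParams(
        fps=cfg.fps,
        position_noise_sd=s.position_noise_sd_mm,
        first_lift_latency_mean_control=s.first_lift_latency_mean_ms,
        first_lift_latency_sd_control=s.first_lift_latency_sd_ms,
    )


def _pert_from_config(cfg: RunConfig) -> PerturbationParams:
    s = cfg.synth
    return PerturbationParams(
        laser_duration=s.laser_duration_ms,
        rebound_latency_mean=s.rebound_latency_mean_ms,
        rebound_latency_sd=s.rebound_latency_sd_ms,
    )


def _load_trajectories(outdir: Path) -> dict:
    path = outdir / "session" / "trajectories.csv"
    if not path.exists():
        return {}
    df = pd.read_csv(path)
    return {tid: g[["x_mm", "y_mm", "z_mm"]].to_numpy()
            for tid, g in df.groupby("trial_id", sort=False)}


def _load_trials(outdir: Path):
    sess = outdir / "session" / "session.json"
    if not sess.exists():
        raise StageError("missing upstream output of stage 'generate' (session.json)")
    return load_session(sess, trajectories=_load_trajectories(outdir))


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: RunConfig, outdir: Path) -> None:
    kin = _kin_from_config(cfg)
    pert = _pert_from_config(cfg)
    s = cfg.synth
    trials = simulate_session(kin, pert, s.n_trials, s.laser_fraction,
                              seed=s.seed, laser_align_epoch=s.laser_align_epoch,
                              n_frames=s.n_frames)
    trials += simulate_rebound_session(kin, pert, s.n_rebound_trials,
                                       seed=s.seed + 1, n_frames=s.n_frames)
    sess_dir = outdir / "session"
    sess_dir.mkdir(parents=True, exist_ok=True)
    save_session(trials, sess_dir / "session.json", fps=cfg.fps)
    rows = []
    for t in trials:
        n = len(t.trajectory3d)
        rows.append(pd.DataFrame({
            "trial_id": t.trial_id, "frame": np.arange(n),
            "x_mm": t.trajectory3d[:, 0], "y_mm": t.trajectory3d[:, 1],
            "z_mm": t.trajectory3d[:, 2]}))
    pd.concat(rows, ignore_index=True).to_csv(sess_dir / "trajectories.csv",
                                              index=False, float_format="%.5f")

    # short video trials for the tracking stages
    scene = SceneParams()
    vid_dir = outdir / "videos"
    for i in range(s.render_trials):
        vt = simulate_trial(kin, None, seed=s.seed + 100 + i,
                            trial_id=f"video{i:02d}", cue_frame=50,
                            n_frames=s.render_frames)
        video = render_stereo_video(vt, scene, seed=s.seed + 200 + i)
        write_video(video, vid_dir, vt.trial_id, seed=s.seed + 200 + i)
    scene.cameras.to_yaml(outdir / "calibration.yaml")


def stage_track(cfg: RunConfig, outdir: Path) -> None:
    vid_dir = outdir / "videos"
    video_ids = sorted(p.name for p in vid_dir.glob("video*") if p.is_dir())
    if not video_ids:
        raise StageError("missing upstream output of stage 'generate' (videos)")
    tb = cfg.tracker
    # assemble a labeled training set from the rendered ground truth,
    # standing in for sparse manual labels
    frames, labels = [], []
    per_video = max(1, tb.n_train_frames // max(1, len(video_ids)) // 2)
    for vid in video_ids:
        gt = pd.read_csv(vid_dir / vid / "ground_truth_tracks.csv")
        for view in ("front", "side"):
            stack = read_frame_stack(vid_dir / vid / view)
            idx = np.linspace(0, len(stack) - 1, per_video).astype(int)
            frames.extend(stack[i] for i in idx)
            labels.extend(gt.loc[i, [f"x_px_{view}", f"y_px_{view}"]].to_numpy()
                          for i in idx)
    model = CascadeTracker(
        n_stages=tb.n_stages, n_ferns=tb.n_ferns, fern_depth=tb.fern_depth,
        n_candidate_features=tb.n_candidate_features,
        n_selected_features=tb.n_selected_features,
        feature_radius=tb.feature_radius,
        augmentations_per_frame=tb.augmentations_per_frame,
        random_state=tb.seed)
    model.fit(frames, np.asarray(labels))
    track_dir = outdir / "tracks"
    track_dir.mkdir(parents=True, exist_ok=True)
    model.to_json(track_dir / "cascade_model.json")
    tc = TrackConfig(n_inits=tb.n_inits, smoothness_weight=tb.smoothness_weight,
                     mode_bandwidth=tb.mode_bandwidth,
                     error_spread_threshold=tb.error_spread_threshold)
    for vid in video_ids:
        for view in ("front", "side"):
            stack = read_frame_stack(vid_dir / vid / view)
            res = model.track_video(stack, tc, seed=tb.seed + 7)
            track_to_frame(res).to_csv(track_dir / f"{vid}_{view}.csv", index=False,
                                       float_format="%.4f")
            with open(track_dir / f"{vid}_{view}_flags.json", "w") as fh:
                json.dump({"flagged_frames": res.flagged}, fh)


def stage_reconstruct(cfg: RunConfig, outdir: Path) -> None:
    vid_dir = outdir / "videos"
    video_ids = sorted(p.name for p in vid_dir.glob("video*") if p.is_dir())
    if not video_ids:
        raise StageError("missing upstream output of stage 'generate' (videos)")
    calib = outdir / "calibration.yaml"
    if cfg.stereo.calibration_file:
        calib = Path(cfg.stereo.calibration_file)
    rig = StereoRig.from_yaml(calib) if calib.exists() else default_rig()
    rec_dir = outdir / "reconstruction"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for vid in video_ids:
        tracks = {}
        for view in ("front", "side"):
            tpath = outdir / "tracks" / f"{vid}_{view}.csv"
            if tpath.exists():
                df = pd.read_csv(tpath)
                tracks[view] = df[["x_px", "y_px"]].to_numpy()
            else:
                # fall back to supplied ground-truth tracks
                gpath = vid_dir / vid / "ground_truth_tracks.csv"
                if not gpath.exists():
                    raise StageError(
                        "missing upstream output of stage 'track' (no tracks or "
                        "ground-truth substitute)")
                gt = pd.read_csv(gpath)
                tracks[view] = gt[[f"x_px_{view}", f"y_px_{view}"]].to_numpy()
        pts, res = triangulate_track(tracks["front"], tracks["side"], rig)
        pd.DataFrame({"frame": np.arange(len(pts)),
                      "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
                      "residual_px": res}).to_csv(
            rec_dir / f"{vid}_3d.csv", index=False, float_format="%.5f")


def stage_analyze(cfg: RunConfig, outdir: Path) -> None:
    trials = _load_trials(outdir)
    a = cfg.analysis
    an_dir = outdir / "analysis"
    an_dir.mkdir(parents=True, exist_ok=True)
    control = [t for t in trials if t.laser_on is None and t.cue is not None]
    laser_cued = [t for t in trials if t.laser_on is not None and t.cue is not None]
    rebound = [t for t in trials if t.cue is None and t.laser_on is not None]
    summary: dict = {"n_control": len(control), "n_laser_cued": len(laser_cued),
                     "n_rebound": len(rebound)}

    # initiation rates and cumulative First-Lift
    win = tuple(a.initiation_window_frames)
    rows = []
    for name, group, ref in (("control", control, "cue"),
                             ("rebound", rebound, "laser_off")):
        if not group:
            continue
        k, n = initiation_rate(group, win, reference=ref)
        rows.append({"condition": name, "initiated": k, "total": n,
                     "rate": k / n if n else np.nan})
        sf = cumulative_first_lift(group, reference=ref, window=win)
        pd.DataFrame({"time_ms": sf.times_ms, "cumulative": sf.counts}).to_csv(
            an_dir / f"cumulative_first_lift_{name}.csv", index=False)
    pd.DataFrame(rows).to_csv(an_dir / "initiation_rates.csv", index=False)

    # first-lift latency comparison control vs rebound
    if control and rebound:
        lat_c = [s.first_lift for s in (interval_stats(t, "cue") for t in control)
                 if s.first_lift is not None]
        lat_r = [s.first_lift for s in (interval_stats(t, "laser_off") for t in rebound)
                 if s.first_lift is not None]
        if len(lat_c) >= 2 and len(lat_r) >= 2:
            stat, pval = compare_distributions(lat_c, lat_r, "rank_sum")
            summary["first_lift_latency"] = {
                "control_median_ms": float(np.median(lat_c)),
                "rebound_median_ms": float(np.median(lat_r)),
                "control_sd_ms": float(np.std(lat_c, ddof=1)),
                "rebound_sd_ms": float(np.std(lat_r, ddof=1)),
                "rank_sum_p": pval,
            }

    # progression histogram for cued laser trials
    if laser_cued and control:
        try:
            progression_histogram(laser_cued, control, seed=a.seed).to_csv(
                an_dir / "progression.csv", index=False)
        except ValueError as e:
            summary.setdefault("warnings", []).append(str(e))

    # targets, matched-control deviation time course and divergence
    with_traj = [t for t in control if t.trajectory3d is not None
                 and t.outcome == "success"]
    if with_traj:
        targets_mean = infer_targets(with_traj, "mean")
        targets_med = infer_targets(with_traj, "median")
        summary["targets"] = {
            "grab_mean_mm": targets_mean.grab_target.tolist(),
            "grab_median_mm": targets_med.grab_target.tolist(),
            "mouth_mean_mm": targets_mean.mouth_target.tolist(),
            "mouth_median_mm": targets_med.mouth_target.tolist(),
        }
        lift_laser = [t for t in laser_cued if t.epoch_at_laser_onset() == "Lift"]
        if lift_laser:
            matched = matched_control_intervals(with_traj, lift_laser, "Lift",
                                                seed=a.seed)
            tc_ctl = deviation_timecourse(matched, targets_med.grab_target,
                                          horizon_ms=a.horizon_ms, fps=cfg.fps)
            tc_las = deviation_timecourse(
                [(t, t.laser_on) for t in lift_laser], targets_med.grab_target,
                horizon_ms=a.horizon_ms, fps=cfg.fps)
            div = divergence_time(tc_ctl, tc_las)
            summary["divergence_time_ms"] = div
            pd.DataFrame({
                "time_ms": tc_ctl.times_ms,
                "control_median": tc_ctl.median, "control_q25": tc_ctl.q25,
                "control_q75": tc_ctl.q75,
                "laser_median": tc_las.median, "laser_q25": tc_las.q25,
                "laser_q75": tc_las.q75,
            }).to_csv(an_dir / "deviation_timecourse.csv", index=False,
                      float_format="%.5f")

        # Grab error and NN accuracy: control vs rebound reaches
        rb_traj = [t for t in rebound if reach_segment(t) is not None]
        if rb_traj:
            dists, summ = grab_error(rb_traj, with_traj)
            dists_c, summ_c = grab_error(with_traj, with_traj)
            summary["grab_error"] = {"rebound": summ, "control": summ_c}
            ok_r = dists[np.isfinite(dists)]
            ok_c = dists_c[np.isfinite(dists_c)]
            if len(ok_r) >= 2 and len(ok_c) >= 2:
                _, pval = compare_distributions(ok_c, ok_r, "rank_sum")
                summary["grab_error"]["rank_sum_p"] = pval
            ctl_aligned = [align_by_arclength(reach_segment(t))
                           for t in with_traj if reach_segment(t) is not None]
            rb_aligned = [align_by_arclength(reach_segment(t)) for t in rb_traj]
            if len(ctl_aligned) >= 2 and len(rb_aligned) >= 2:
                summary["nn_balanced_accuracy"] = nn_balanced_accuracy(
                    ctl_aligned, rb_aligned, a.nn_checkpoint)

    # ephys block
    e = cfg.ephys
    sp = SpikeSimParams(baseline_rate=e.baseline_rate_hz,
                        suppression_fraction=e.suppression_fraction,
                        rebound_gain=e.rebound_gain,
                        rebound_duration=e.rebound_duration_ms,
                        laser_window=tuple(e.laser_window_frames),
                        n_trials=e.n_trials, seed=e.seed, fps=cfg.fps,
                        trial_duration_s=e.trial_duration_s)
    trains = simulate_spike_trains(sp)
    t_on = sp.laser_window[0] / sp.fps
    t_off = sp.laser_window[1] / sp.fps
    p = psth(trains, 0.0, (0.0, sp.trial_duration_s), bin_s=0.1)
    p.to_frame().to_csv(an_dir / "psth.csv", index=False, float_format="%.5f")
    supp, reb = rebound_modulation(
        p, baseline_window=(0.0, t_on), laser_window=(t_on, t_off),
        post_window=(t_off, t_off + e.rebound_duration_ms / 1000.0))
    summary["ephys"] = {"suppression_ratio": supp, "rebound_ratio": reb,
                        "laser_on_s": t_on, "laser_off_s": t_off}

    with open(an_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    from .report import build_report

    if not (outdir / "session" / "session.json").exists():
        raise StageError("missing upstream output of stage 'generate' (session.json)")
    build_report(cfg, outdir)


_STAGE_FUNCS = {
    "generate": stage_generate,
    "track": stage_track,
    "reconstruct": stage_reconstruct,
    "analyze": stage_analyze,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, resume: bool = False) -> RunManifest:
    """Execute the configured stages in dependency order and write a manifest.

    With ``resume=True`` a stage is skipped when its completion marker
    exists and records the same configuration hash.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    manifest = RunManifest(config_hash=chash)
    for stage in config.stages:
        marker = outdir / f".stage_{stage}.json"
        if resume and marker.exists():
            with open(marker) as fh:
                if json.load(fh).get("config_hash") == chash:
                    log.info("stage %s: up to date, skipping", stage)
                    continue
        t0 = time.monotonic()
        log.info("stage %s: running", stage)
        _STAGE_FUNCS[stage](config, outdir)
        log.info("stage %s: done in %.1f s", stage, time.monotonic() - t0)
        with open(marker, "w") as fh:
            json.dump({"config_hash": chash}, fh)
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and not path.name.startswith(".stage_") \
                and path.name != "manifest.json":
            manifest.files[str(path.relative_to(outdir))] = _sha256(path)
    manifest.to_json(outdir / "manifest.json")
    return manifest
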