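"""Figures and tables summarizing a pipeline run.

Plots mirror the standard presentation of this kind of experiment:
per-trial ethograms, cumulative First-Lift histograms, 3D trajectory
renders, deviation-from-target time courses, and PSTHs around the laser.
CSV tables are written deterministically so regeneration from the same
run directory is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .config import RunConfig  # noqa: E402
from .ethogram import CANONICAL_EPOCHS, Trial, load_session  # noqa: E402

EPOCH_COLORS = {
    "Lift": "#d62728", "HandOpen": "#ff7f0e", "Grab": "#2ca02c",
    "Supinate": "#1f77b4", "AtMouth": "#9467bd", "Chew": "#8c564b",
    "ChewNoPellet": "#c49c94", "Lick": "#e377c2", "Groom": "#7f7f7f",
}


def _ethogram_axes(ax, trials: list[Trial], fps: float, title: str) -> None:
    for row, t in enumerate(trials):
        ref = t.cue if t.cue is not None else (t.laser_off or 0)
        if t.laser_on is not None:
            ax.plot([(t.laser_on - ref) / fps, (t.laser_off - ref) / fps],
                    [row + 0.45, row + 0.45], color="deepskyblue", lw=2)
        for e in t.epochs:
            ax.plot([(e.start - ref) / fps, (e.end - ref) / fps], [row, row],
                    color=EPOCH_COLORS.get(e.label, "k"), lw=4, solid_capstyle="butt")
    ax.set_xlabel("time from reference (s)")
    ax.set_ylabel("trial")
    ax.set_title(title)


def build_report(cfg: RunConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    rep = outdir / "report"
    rep.mkdir(parents=True, exist_ok=True)
    from .pipeline import _load_trajectories  # local import to avoid cycle

    trials = load_session(outdir / "session" / "session.json",
                          trajectories=_load_trajectories(outdir))
    fps = cfg.fps
    control = [t for t in trials if t.laser_on is None and t.cue is not None]
    laser = [t for t in trials if t.laser_on is not None]
    produced = []

    if trials:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
        _ethogram_axes(axes[0], control[:20], fps, "control trials")
        _ethogram_axes(axes[1], laser[:20], fps, "laser trials")
        fig.tight_layout()
        fig.savefig(rep / "ethograms.png", dpi=110)
        plt.close(fig)
        produced.append("ethograms.png")

    an_dir = outdir / "analysis"
    for name in ("control", "rebound"):
        path = an_dir / f"cumulative_first_lift_{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        fig, ax = plt.subplots(figsize=(4, 3))
        if len(df):
            ax.step(df["time_ms"], df["cumulative"], where="post")
        ax.set_xlabel("First Lift latency (ms)")
        ax.set_ylabel("cumulative trials")
        ax.set_title(f"cumulative First Lift ({name})")
        fig.tight_layout()
        fig.savefig(rep / f"cumulative_first_lift_{name}.png", dpi=110)
        plt.close(fig)
        produced.append(f"cumulative_first_lift_{name}.png")

    with_traj = [t for t in control if t.trajectory3d is not None][:25]
    if with_traj:
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(projection="3d")
        for t in with_traj:
            ax.plot(*t.trajectory3d[::4].T, lw=0.5, alpha=0.6, color="gray")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_zlabel("z (mm)")
        ax.set_title("control reach trajectories")
        fig.tight_layout()
        fig.savefig(rep / "trajectories3d.png", dpi=110)
        plt.close(fig)
        produced.append("trajectories3d.png")

    dev = an_dir / "deviation_timecourse.csv"
    if dev.exists():
        df = pd.read_csv(dev)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for cond, color in (("control", "gray"), ("laser", "deepskyblue")):
            ax.plot(df["time_ms"], df[f"{cond}_median"], color=color, label=cond)
            ax.fill_between(df["time_ms"], df[f"{cond}_q25"], df[f"{cond}_q75"],
                            color=color, alpha=0.25, lw=0)
        ax.set_xlabel("time from laser onset (ms)")
        ax.set_ylabel("distance to target (mm)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(rep / "deviation_timecourse.png", dpi=110)
        plt.close(fig)
        produced.append("deviation_timecourse.png")

    psth_path = an_dir / "psth.csv"
    if psth_path.exists():
        df = pd.read_csv(psth_path)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.bar(df["bin_start_s"], df["rate_hz"],
               width=df["bin_end_s"] - df["bin_start_s"], align="edge",
               color="dimgray")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("rate (Hz)")
        ax.set_title("population PSTH (100 ms bins)")
        fig.tight_layout()
        fig.savefig(rep / "psth.png", dpi=110)
        plt.close(fig)
        produced.append("psth.png")

    # summary tables (deterministic CSV re-exports)
    tables = {}
    for src in sorted(an_dir.glob("*.csv")) if an_dir.exists() else []:
        df = pd.read_csv(src)
        dst = rep / f"table_{src.name}"
        df.to_csv(dst, index=False)
        tables[src.name] = f"table_{src.name}"
    missing = [n for n in ("initiation_rates.csv", "psth.csv") if n not in tables]
    for name in missing:
        warnings.warn(f"report table {name} skipped: analysis output missing")

    with open(rep / "report.json", "w") as fh:
        json.dump({"figures": produced, "tables": tables,
                   "skipped_tables": missing}, fh, indent=1)
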