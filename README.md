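# reachtrack

Markerless forelimb tracking and trial statistics for head-fixed mouse
prehension experiments with optogenetic perturbation.

In the paradigm this package supports, a head-fixed, food-deprived mouse
reaches for a pellet after an auditory cue while two perpendicular
high-speed cameras (500 frames/s, 352 × 260 px) film the movement. The
behavior decomposes into canonical components — Lift, Hand open, Grab,
Supinate, At mouth, Chew — annotated as epochs on each trial. Brief
optogenetic activation of cortical inhibitory neurons silences sensorimotor
cortex: movement in progress freezes after a short latency, and at laser
offset a complete "rebound" reach is often launched, even without cue or
pellet. `reachtrack` provides the full computational chain for analyzing
such experiments, exercised end-to-end on a synthetic-data generator, since
raw videos of this kind are rarely shared:

- **`reachtrack.synth`** — generator for trials (minimum-jerk multi-epoch
  reaches, laser-induced freezing, rebound reaches), rendered stereo video
  (Gaussian hand blob over noise), and laser-modulated Poisson spike trains.
- **`reachtrack.tracker`** — a Cascaded Pose Regression (CPR) hand tracker.
  A cascade of `T = 100` random-fern regressors refines a pose estimate
  from pose-indexed intensity-difference features. Each frame is tracked
  from `K = 50` random initializations; mean-shift clustering of the final
  estimates yields candidate modes, and dynamic programming selects one
  mode per frame minimizing
  `Σ_t [−log w_t(m) + λ‖p_t − p_{t−1}‖²]`,
  flagging low-confidence or jumping frames for re-tracking or manual
  correction. `CascadeTracker` is a scikit-learn-style estimator
  (`fit`/`track_video`, `get_params`).
- **`reachtrack.stereo`** — pinhole cameras with two-term radial
  distortion, least-squares triangulation with reprojection residuals, and
  per-animal calibration refinement.
- **`reachtrack.ethogram`** — the trial/epoch data model: validation
  against the canonical ordering, First-Lift latencies and component
  intervals, initiation rates, cumulative First-Lift histograms, and
  epoch-progression histograms with seeded count-matched control sampling.
- **`reachtrack.kinematics`** — target inference from control trials,
  matched-control distance-to-target time courses, the interquartile
  divergence time, arc-length trajectory alignment, leave-one-out 1-NN
  balanced accuracy `(TPR + TNR)/2`, Grab end-point error, and
  rank-sum / Welch / Fligner–Killeen two-sample tests.
- **`reachtrack.ephys`** — trough-to-peak spike-width classification
  (fast-spiking < 0.35 ms, pyramidal > 0.45 ms, boundary band excluded),
  PSTHs in 100-ms bins, and suppression/rebound rate ratios.
- **`reachtrack.pipeline` / CLI `reachtrack`** — reproducible staged runs
  (`generate → track → reconstruct → analyze → report`) with a checksum
  manifest.

## Worked example

```python
import numpy as np
from reachtrack.synth import (ReachKinematicsParams, PerturbationParams,
                              simulate_control_session, simulate_rebound_session)
from reachtrack.ethogram import interval_stats
from reachtrack.kinematics import compare_distributions

kin = ReachKinematicsParams()          # 500 fps, perch -> pellet -> mouth
pert = PerturbationParams(laser_duration=2000.0,
                          rebound_prob_vs_duration={2000.0: 1.0})
control = simulate_control_session(kin, 50, seed=0, n_frames=1500)
rebound = simulate_rebound_session(kin, pert, 50, seed=1, n_frames=2600)

lat_c = [interval_stats(t, "cue").first_lift for t in control]
lat_r = [interval_stats(t, "laser_off").first_lift for t in rebound]
print(f"control First Lift: {np.median(lat_c):.0f} ms (sd {np.std(lat_c):.0f})")
print(f"rebound First Lift: {np.median(lat_r):.0f} ms (sd {np.std(lat_r):.0f})")
print("rank-sum p = %.2g" % compare_distributions(lat_c, lat_r, "rank_sum")[1])
```

prints

```
control First Lift: 391 ms (sd 107)
rebound First Lift: 251 ms (sd 48)
rank-sum p = 3.2e-10
```

i.e. rebound reaches start sooner after laser offset (median 251 ms vs
391 ms after the cue) and with less jitter — the generator's rebound
latency distribution, recovered by the interval statistics.

A full staged run, writing videos, tracks, 3D trajectories, analysis
tables and figures plus a `manifest.json` of checksums:

```sh
reachtrack all --seed 1 --outdir runs/demo
```

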