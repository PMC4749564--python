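# Methods

This note documents the models, conventions and numerical choices behind
`reachtrack`, and what the synthetic-data generator does and does not
emulate.

## The behavioral model

A trial is a timeline at 500 frames/s. Control (cued) trials rest at the
perch, initiate after a First-Lift latency drawn from a truncated Gaussian
(mean 400 ms, SD 120 ms, floor 50 ms, clamp at +4 SD), and execute the
canonical component sequence Lift → Hand open → Grab → Supinate → At mouth
→ Chew as consecutive epochs. Epoch durations are log-normal with means
100 / 120 / 80 / 100 / 200 / 800 ms and a common coefficient of variation
of 0.08; trained head-fixed prehension is strongly stereotyped, and ~10%
timing variability is what reach-to-grasp studies in rodents and primates
typically report for overtrained movements. The hand path is built from
minimum-jerk segments (position profile `10t³ − 15t⁴ + 6t⁵`): perch →
pellet between the Lift start and the Grab start, a hold at the pellet
through Grab, pellet → mouth between the Supinate start and the At-mouth
start. Minimum jerk is the standard smooth-reach model; the real
trajectory shape is not parameterized by any published value, so this is a
convention, not an inference. Gaussian position noise (SD 0.15 mm per
axis and frame) represents tracking error and tremor. By construction the
hand position at the Grab start equals the pellet position plus noise,
which is what the target-inference step assumes.

Default geometry (mm, world origin at the perch, right-handed): pellet at
(10, 6, −2), mouth at (1, 3, 7) — a ~12 mm reach, typical of the task.

### Laser perturbation semantics

A laser window either precedes movement, strikes mid-movement, or falls
during chewing:

- **Pre-movement**: initiation is withheld for the laser's duration.
- **Mid-movement**: the hand freezes. The drawn freeze latency (uniform
  on 72–170 ms by default, the observable latency range) is the time at
  which the hand *is* frozen: velocity decays exponentially with a 6-ms
  time constant beginning 30 ms (five time constants) before that point.
  Epochs that started before the decay begins are kept (truncated); later
  ones never occur. Optionally (off by default) the limb then drifts to a
  fixed mid-air point, emulating the retraction seen under prolonged
  suppression; the endpoint (midpoint of perch and pellet, raised 3 mm)
  is a convention, as no measured endpoint exists.
- **During chewing**: no kinematic effect; such trials are the ones the
  matched-control exclusion rule removes from Lift–Supinate groups.

After laser offset, a rebound reach occurs with a probability interpolated
from a duration→probability table (defaults 0.2 / 0.5 / 0.9 / 0.95 at
0.5 / 1 / 2 / 4 s — at least ~2 s of silencing is needed for >90% rebound
rates), after a Normal(250, 50) ms latency: shorter and less variable than
the cued latency, which is the signature the timing statistics must
recover. The rebound reach runs the full component sequence from the
current hand position toward the pellet (plus an optional injected offset)
and mouth.

### What the generator does not emulate

Photorealistic appearance (the hand is a Gaussian blob), digits and limb
articulation, licking/grooming kinematics, failure modes such as missed
grabs or pellet drops, session-level learning or satiety drift, and any
tissue optics. Tests passing on this generator demonstrate that the
analysis chain recovers known ground truth under its statistical
assumptions — not that the tracker would reach the same accuracy on real
near-infrared video.

## Tracker

Cascaded pose regression with random ferns. Features are pose-indexed
intensity differences: pairs of offsets within a 60-px radius of the
current pose, sampled with radius `R·u²` so the pool mixes long-range
context features with the short-range features needed for sub-blob
localization; out-of-bounds samples clamp to the nearest pixel, making
features translation-equivariant. Each of the 100 stages draws a fresh
400-feature pool, keeps the 40 features most correlated with the residual
displacement (the feature-selection rule is a documented stand-in; the
original method's rule is unpublished), and fits 50 depth-5 ferns whose
thresholds are drawn between the 20th and 80th feature percentiles; bin
outputs are shrunken residual means (`sum/(count + 5)`), and the stage
update is the fern average. Training poses are 10 per labeled frame: half
Gaussian around the label (SD 20 px), half uniform over the image, so the
cascade learns both coarse attraction and fine refinement; the median
training error is logged per stage and is non-increasing (0.5 px
tolerance).

Tracking runs the cascade from 50 uniform initializations per frame (the
initialization distribution is unspecified in the source method; uniform
is the weakest assumption), clusters the final estimates by mean shift
(bandwidth 5 px; modes merged within half a bandwidth; ties broken toward
the previous frame, else lowest (y, x)), and selects one mode per frame by
a Viterbi pass over `−log(weight fraction) + λ‖Δp‖²` with λ = 0.01 px⁻².
Frames whose selected mode holds less than 40% of the initializations, or
that jump more than 25 px, are flagged; a second pass re-tracks flagged
frames from initializations drawn around the interpolation of their
unflagged neighbors. Manual corrections pin a frame (confidence 1) and
re-run the DP with the pin as a hard constraint. λ trades temporal
smoothness against per-frame evidence: at 500 frames/s real movement is a
few px/frame, so a 50-px excursion costs ~25 against a log-weight scale of
a few units, while genuine motion costs ≪ 1.

## Stereo geometry

Standard pinhole model with two-term radial distortion (the minimal common
case of the usual calibration toolboxes), world-to-camera convention
`x_cam = R x + t`. Triangulation undistorts by fixed-point iteration,
solves the linear least-squares ray intersection, rejects near-parallel
geometry by the condition number of the normal matrix (threshold 1e6), and
refines by Levenberg–Marquardt on the four pixel residuals; the RMS
reprojection residual is reported per frame. Calibration refinement holds
the front camera fixed (it anchors the world frame — adjusting both
cameras is gauge-degenerate when the 3D points are re-triangulated) and
optimizes the side camera's extrinsics; a flag releases the intrinsics of
both cameras, off by default to avoid overfitting a single session's
trajectories. Refinement requires ≥ 20 non-collinear correspondences and
never returns a rig worse than its input.

## Ethogram statistics

Frames are 0-based; epochs are half-open `[start, end)`; times are
reported in ms at the session fps. A trial "achieves" an epoch iff an
interval with that label exists; canonical ordering is enforced on first
frames only, since component definitions reference first frames and epochs
may overlap. The "final prehension sequence" is resolved greedily from the
last Lift. First Lift is the first Lift at or after the reference event
(cue for control, laser offset for rebound); initiation windows are
half-open in frames relative to the reference. Progression histograms
group laser trials by the last component initiated at or before laser
onset, drop Lift–Supinate-group trials whose Chew overlaps the laser (no
inhibition), and draw per-animal control subsamples of matching size with
a seeded RNG, restricted to controls achieving the grouping epoch; if an
animal has fewer eligible controls than laser trials the sample is drawn
with replacement under a warning. All rates are exact integer counts.

## Kinematic comparison

Targets are the per-axis mean (default) or median hand position at the
Grab / At-mouth starts of control trials; both are reported, as both
summaries are in common use. Matched control intervals follow the
construction: per control trial, one laser trial is drawn uniformly
(seeded), its offset t (laser onset minus last preceding grouping-epoch
start) is applied to a uniformly drawn epoch instance of the control
trial. Deviation time courses are pointwise Euclidean distances to the
target with median and quartiles across trials on the per-frame (2 ms)
grid; the divergence time is the first time from which the two
interquartile bands stay disjoint through the horizon (default 250 ms for
reach-directed groups — long enough to cover the freeze, short enough not
to reach the controls' pellet-to-mouth transfer, which re-widens their
band). Arc-length alignment normalizes cumulative chord length to [0, 1]
(zero-length steps collapsed) and interpolates at checkpoints
{0, 1/3, 2/3, 1}. The 1-NN comparison is leave-one-out within the pooled
set (without LOO a trial would match itself) on 3D positions at a
checkpoint; balanced accuracy `(TPR + TNR)/2` makes 0.5 chance regardless
of group sizes. The per-replicate classifier summary is the mean over the
four standard checkpoints, with per-checkpoint values also reported. Grab
error is the distance to the per-axis median control-success Grab
position, summarized by median and MAD. Two-sample location tests:
Wilcoxon–Mann–Whitney (exact null when pooled n ≤ 20 without ties, normal
approximation with tie correction otherwise) and Welch's t; dispersion:
Fligner–Killeen, which unlike Ansari–Bradley remains valid when the
locations differ, as they do between control and rebound latencies.
Per-transition comparisons are reported uncorrected (matching common
presentation); Holm adjustment is available but off by default.

## Ephys

Spike width is the interval from the global trough to the global maximum
of the mean waveform (which must follow the trough), in ms. Classes:
< 0.35 ms fast-spiking, > 0.45 ms putative pyramidal, the closed band
[0.35, 0.45] excluded — the boundary inequalities are strict on both
sides. PSTHs pool spikes across trials in half-open 100-ms bins (edge
spikes belong to the right bin) and divide by `n_trials · bin`;
suppression and rebound ratios are window-mean rates over the baseline
mean, undefined (with warning) at zero baseline. Band-pass filtering and
threshold detection are provenance requirements of the input spike times,
not implemented: sorting is upstream of this package.

## Pipeline and problem sizes

Stages run in dependency order with per-stage seeds; the manifest records
a configuration hash (excluding the output location) and a SHA-256 per
output file, so identical configurations and seeds reproduce identical
manifests. If 2D tracks are absent at reconstruction, supplied
ground-truth tracks are used, so kinematic analyses run with tracking
disabled. The test suite and the acceptance script use desk-scale problem
sizes chosen to give stable statistics: 100–200 labeled training frames
and a 500-frame held-out stereo video for the tracker; 1000 random
instances for the DP oracle; 1000 points for stereo Monte Carlo; 50
trials/condition × 10 seeds for divergence recovery; 100 replicates of
50/50 trials for NN calibration; 50 and 100 replicates for the timing and
end-point calibrations; 100 trials for spike-train recovery.

## Known limitations

The tracker is single-point (no digits or articulation) and its
feature-selection rule is a stand-in for an unpublished one; tracking
accuracy is only demonstrated on blob-on-noise renders. The freeze
velocity profile and the retraction endpoint are conventions. The
divergence-time statistic is a conservative detector whose delay grows
with kinematic variability; under weakly stereotyped behavior it reports
later times than the true freeze latency. Unit-count bookkeeping across
recording sessions is reported as exact counts only; no attempt is made to
reconcile inconsistent external denominators.
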