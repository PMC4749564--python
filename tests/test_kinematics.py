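"""Targets, matched controls, deviation/divergence, arc-length alignment,
nearest-neighbor balanced accuracy, Grab error, and two-sample tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from reachtrack.ethogram import EpochInterval, Trial
from reachtrack.kinematics import (AlignedTrajectory, DeviationTimecourse,
                                   align_by_arclength, compare_distributions,
                                   deviation_timecourse, divergence_time,
                                   grab_error, infer_targets,
                                   matched_control_intervals,
                                   nn_balanced_accuracy, reach_segment)
from reachtrack.synth import (PerturbationParams, simulate_control_session,
                              simulate_perturbed_session)


def trial_with_traj(traj, epochs, trial_id="t0", laser=None):
    eps = [EpochInterval(label=l, start=s, end=e) for (l, s, e) in epochs]
    laser_on, laser_off = laser if laser else (None, None)
    return Trial(trial_id=trial_id, cue=10, laser_on=laser_on,
                 laser_off=laser_off, epochs=eps,
                 trajectory3d=np.asarray(traj, float))


def static_trial(pos, n=200, trial_id="t0", **kw):
    traj = np.tile(np.asarray(pos, float), (n, 1))
    return trial_with_traj(traj, [("Lift", 20, 50), ("HandOpen", 50, 80),
                                  ("Grab", 80, 110), ("Supinate", 110, 140),
                                  ("AtMouth", 140, 170)],
                           trial_id=trial_id, **kw)


class TestInferTargets:
    def test_shared_position_recovered_by_both_estimators(self):
        trials = [static_trial([1.0, 2.0, 3.0], trial_id=f"t{i}") for i in range(5)]
        for est in ("mean", "median"):
            tp = infer_targets(trials, est)
            np.testing.assert_allclose(tp.grab_target, [1.0, 2.0, 3.0])

    def test_median_resists_gross_outlier(self, kin):
        rng = np.random.default_rng(0)
        trials = []
        for i in range(20):
            traj = np.tile(kin.pellet_pos, (200, 1)) + rng.normal(0, 0.1, (200, 3))
            trials.append(trial_with_traj(
                traj, [("Lift", 20, 50), ("Grab", 80, 110), ("Supinate", 110, 140),
                       ("AtMouth", 140, 170)], trial_id=f"t{i}"))
        out = trials[0].trajectory3d
        out[80] = kin.pellet_pos + np.array([50.0, 0.0, 0.0])  # gross outlier
        tp_med = infer_targets(trials, "median")
        tp_mean = infer_targets(trials, "mean")
        assert np.linalg.norm(tp_med.grab_target - kin.pellet_pos) < 0.2
        assert np.linalg.norm(tp_mean.grab_target - kin.pellet_pos) > 1.0

    def test_recovers_generator_pellet_position(self, kin):
        n = 40
        trials = [t for t in simulate_control_session(kin, n, seed=1, n_frames=1500)
                  if t.outcome == "success"]
        tp = infer_targets(trials, "mean")
        tol = 3 * kin.position_noise_sd / np.sqrt(len(trials))
        assert np.all(np.abs(tp.grab_target - kin.pellet_pos) <= 4 * tol)

    def test_no_eligible_trials_error(self):
        with pytest.raises(ValueError, match="eligible"):
            infer_targets([])


class TestMatchedControls:
    def _laser_trials(self, offsets):
        out = []
        for i, off in enumerate(offsets):
            lift = 200
            out.append(trial_with_traj(
                np.zeros((2000, 3)), [("Lift", lift, lift + 60)],
                trial_id=f"l{i}", laser=(lift + off, lift + off + 1000)))
        return out

    def test_zero_offsets_start_at_epoch_starts(self):
        lasers = self._laser_trials([0, 0, 0])
        controls = [static_trial([0, 0, 0], trial_id=f"c{i}") for i in range(10)]
        pairs = matched_control_intervals(controls, lasers, "Lift", seed=0)
        assert len(pairs) == 10
        for trial, start in pairs:
            assert start == trial.epochs_with("Lift")[0].start

    def test_fixed_seed_reproducible(self):
        lasers = self._laser_trials([5, 10, 15])
        controls = [static_trial([0, 0, 0], trial_id=f"c{i}") for i in range(20)]
        p1 = matched_control_intervals(controls, lasers, "Lift", seed=7)
        p2 = matched_control_intervals(controls, lasers, "Lift", seed=7)
        assert [(t.trial_id, s) for t, s in p1] == [(t.trial_id, s) for t, s in p2]

    def test_offset_distribution_matches_laser_trials(self):
        offsets = [10, 20, 30]
        lasers = self._laser_trials(offsets)
        controls = [static_trial([0, 0, 0], trial_id=f"c{i:04d}")
                    for i in range(1000)]
        pairs = matched_control_intervals(controls, lasers, "Lift", seed=1)
        assigned = [s - t.epochs_with("Lift")[0].start for t, s in pairs]
        counts = [assigned.count(o) for o in offsets]
        assert sum(counts) == 1000
        _, p = stats.chisquare(counts)  # uniform over the three laser trials
        assert p > 1e-3

    def test_chew_during_laser_excluded_for_early_groups(self):
        lasers = self._laser_trials([10, 10])
        chew = trial_with_traj(
            np.zeros((2000, 3)),
            [("Lift", 200, 260), ("Chew", 400, 900)],
            trial_id="chewy", laser=(210, 1210))
        controls = [static_trial([0, 0, 0], trial_id=f"c{i}") for i in range(50)]
        pairs = matched_control_intervals(controls, lasers + [chew], "Lift", seed=2)
        assigned = {s - t.epochs_with("Lift")[0].start for t, s in pairs}
        assert assigned == {10}

    def test_control_without_epoch_skipped_with_warning(self):
        lasers = self._laser_trials([0])
        no_lift = trial_with_traj(np.zeros((200, 3)), [("Chew", 20, 50)],
                                  trial_id="nl")
        with pytest.warns(UserWarning, match="lacks epoch"):
            pairs = matched_control_intervals([no_lift], lasers, "Lift", seed=0)
        assert pairs == []


class TestDeviation:
    def test_hand_at_target_gives_zero(self):
        trials = [(static_trial([2.0, 2.0, 2.0], trial_id=f"t{i}"), 20)
                  for i in range(5)]
        tc = deviation_timecourse(trials, [2.0, 2.0, 2.0], horizon_ms=100)
        np.testing.assert_allclose(tc.median, 0.0)
        np.testing.assert_allclose(tc.q75, 0.0)

    def test_frozen_hand_gives_constant_distance(self):
        trials = [(static_trial([3.0, 0.0, 0.0], trial_id=f"t{i}"), 20)
                  for i in range(5)]
        tc = deviation_timecourse(trials, [0.0, 0.0, 0.0], horizon_ms=100)
        np.testing.assert_allclose(tc.median, 3.0)

    def test_horizon_truncation_warns(self):
        trials = [(static_trial([1.0, 0.0, 0.0], n=50, trial_id="t0"), 20)]
        with pytest.warns(UserWarning, match="truncat"):
            tc = deviation_timecourse(trials, [0, 0, 0], horizon_ms=1000)
        assert len(tc.times_ms) == 30

    def test_quartile_ordering_enforced(self):
        with pytest.raises(ValueError, match="quartile"):
            DeviationTimecourse(times_ms=np.arange(3.0),
                                median=np.array([1.0, 1.0, 1.0]),
                                q25=np.array([2.0, 0.0, 0.0]),
                                q75=np.array([3.0, 3.0, 3.0]))


class TestDivergence:
    def _tc(self, med, half_width=0.5):
        med = np.asarray(med, float)
        return DeviationTimecourse(times_ms=np.arange(len(med)) * 2.0,
                                   median=med, q25=med - half_width,
                                   q75=med + half_width)

    def test_identical_timecourses_never_diverge(self):
        a = self._tc(np.linspace(5, 0, 50))
        assert divergence_time(a, a) is None

    def test_disjoint_from_onset_is_zero(self):
        a = self._tc(np.full(20, 1.0))
        b = self._tc(np.full(20, 10.0))
        assert divergence_time(a, b) == 0.0

    def test_reoverlap_pushes_divergence_later(self):
        a = self._tc(np.concatenate([np.zeros(10), np.full(10, 5.0),
                                     np.zeros(5), np.full(15, 5.0)]))
        b = self._tc(np.zeros(40))
        assert divergence_time(a, b) == pytest.approx(2.0 * 25)

    def test_grid_mismatch_error(self):
        a = self._tc(np.zeros(10))
        b = self._tc(np.zeros(12))
        with pytest.raises(ValueError, match="grid"):
            divergence_time(a, b)

    def test_recovers_injected_freeze_latency(self, kin):
        pert = PerturbationParams(laser_duration=2000.0,
                                  freeze_latency_range=(120.0, 120.0),
                                  rebound_prob_vs_duration={2000.0: 0.0})
        laser = simulate_perturbed_session(kin, pert, 50, seed=0,
                                           laser_align_epoch="Lift")
        ctl = [t for t in simulate_control_session(kin, 50, seed=100)
               if t.outcome == "success"]
        targets = infer_targets(ctl, "median")
        matched = matched_control_intervals(ctl, laser, "Lift", seed=0)
        tc_c = deviation_timecourse(matched, targets.grab_target, horizon_ms=250)
        tc_l = deviation_timecourse([(t, t.laser_on) for t in laser],
                                    targets.grab_target, horizon_ms=250)
        div = divergence_time(tc_c, tc_l)
        assert div is not None
        assert abs(div - 120.0) <= 22.0  # one 2 ms grid step + 20 ms


class TestArcLength:
    def test_straight_line_even_checkpoints(self):
        seg = np.linspace([0, 0, 0], [9, 0, 0], 10)
        at = align_by_arclength(seg, checkpoints=(0.0, 1 / 3, 2 / 3, 1.0))
        np.testing.assert_allclose(at.positions[:, 0], [0, 3, 6, 9], atol=1e-9)

    def test_reparameterization_invariance(self):
        t = np.linspace(0, 1, 2001)
        path = np.column_stack([np.sin(2 * t), t ** 2, np.cos(t)])
        slow = path
        fast = path[::2]  # same path traversed at doubled speed
        a1 = align_by_arclength(slow)
        a2 = align_by_arclength(fast)
        np.testing.assert_allclose(a1.positions, a2.positions, atol=1e-4)

    def test_dense_resampling_recovers_fractions(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 2000)
        path = np.column_stack([np.cumsum(rng.normal(0, 0.01, 2000)),
                                np.sin(3 * t), t])
        at = align_by_arclength(path, checkpoints=np.linspace(0, 1, 9))
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        s = np.concatenate([[0], np.cumsum(steps)]) / steps.sum()
        for frac, pos in zip(at.checkpoints, at.positions):
            i = np.argmin(np.abs(s - frac))
            assert np.linalg.norm(pos - path[i]) <= steps.max() * 2

    def test_zero_length_error(self):
        with pytest.raises(ValueError, match="zero"):
            align_by_arclength(np.zeros((10, 3)))

    def test_fractions_must_increase(self):
        with pytest.raises(ValueError):
            AlignedTrajectory(checkpoints=[0.0, 0.5, 0.5, 1.0],
                              positions=np.zeros((4, 3)))


class TestNearestNeighbor:
    def _groups(self, rng, n=50, offset=0.0):
        def grp(shift):
            out = []
            for _ in range(n):
                start = rng.normal(0, 0.1, 3)
                end = np.array([10.0, 0, 0]) + shift + rng.normal(0, 0.1, 3)
                seg = np.linspace(start, end, 30)
                out.append(align_by_arclength(seg))
            return out
        return grp(0.0), grp(np.array([offset, 0, 0]))

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(3)
        a, b = self._groups(rng)
        acc = nn_balanced_accuracy(a, b, 1.0)
        assert 0.3 <= acc <= 0.7

    def test_perfect_separation(self):
        rng = np.random.default_rng(4)
        a, b = self._groups(rng, offset=10.0)
        assert nn_balanced_accuracy(a, b, 1.0) == 1.0

    def test_relabel_and_order_invariance(self):
        rng = np.random.default_rng(5)
        a, b = self._groups(rng, n=20, offset=0.3)
        acc = nn_balanced_accuracy(a, b, 1.0)
        assert nn_balanced_accuracy(b, a, 1.0) == pytest.approx(acc)
        perm = [a[i] for i in rng.permutation(len(a))]
        assert nn_balanced_accuracy(perm, b, 1.0) == pytest.approx(acc)

    def test_majority_classifier_anchor(self):
        # balanced accuracy of an always-majority rule is 0.5 by definition
        tpr, tnr = 1.0, 0.0
        assert (tpr + tnr) / 2 == 0.5

    def test_small_group_error(self):
        rng = np.random.default_rng(6)
        a, b = self._groups(rng, n=2)
        with pytest.raises(ValueError, match="at least 2"):
            nn_balanced_accuracy(a[:1], b, 1.0)


class TestGrabError:
    def test_trial_at_median_is_zero(self):
        ref = [static_trial([1.0, 1.0, 1.0], trial_id=f"r{i}") for i in range(5)]
        d, summ = grab_error([ref[0]], ref)
        assert d[0] == pytest.approx(0.0)
        assert summ["median_mm"] == pytest.approx(0.0)

    def test_axis_offset_distance(self):
        ref = [static_trial([0.0, 0.0, 0.0], trial_id=f"r{i}") for i in range(5)]
        probe = static_trial([0.0, 1.0, 0.0], trial_id="p")
        d, _ = grab_error([probe], ref)
        assert d[0] == pytest.approx(1.0)

    def test_empty_reference_error(self):
        probe = static_trial([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="reference"):
            grab_error([probe], [])


class TestCompareDistributions:
    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = compare_distributions([1.0, 1.0, 1.0], [1.0, 1.0], "rank_sum")
        assert p == 1.0

    def test_exact_rank_sum_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = compare_distributions(a, b, "rank_sum")
        # oracle: enumerate all C(6,3) = 20 assignments of ranks to group a;
        # two-sided p = P(|W - E[W]| >= |w_obs - E[W]|) under the null
        combos = list(itertools.combinations(range(1, 7), 3))
        w_obs = sum(stats.rankdata(a + b)[:3])   # = 6, the minimum
        mean_w = np.mean([sum(c) for c in combos])
        extreme = sum(1 for c in combos
                      if abs(sum(c) - mean_w) >= abs(w_obs - mean_w))
        p_oracle = extreme / len(combos)
        assert p_oracle == pytest.approx(0.1)
        assert p == pytest.approx(p_oracle)

    def test_welch_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 3, 20)
            _, p = compare_distributions(a, b, "welch_t")
            rejections += p < 0.05
        rate = rejections / n_rep
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= ci + 0.01

    def test_unknown_method_error(self):
        with pytest.raises(ValueError, match="method"):
            compare_distributions([1, 2], [3, 4], "bogus")


class TestReachSegment:
    def test_segment_spans_lift_to_grab(self, kin):
        trial = simulate_control_session(kin, 1, seed=12, n_frames=1500)[0]
        seg = reach_segment(trial)
        chain = trial.final_prehension_sequence()
        assert len(seg) == chain["Grab"] - chain["Lift"] + 1
        np.testing.assert_allclose(seg[0], trial.trajectory3d[chain["Lift"]])
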