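"""Cascade tracker: pose-indexed features, training, mode clustering,
DP smoothing against exhaustive enumeration, corrections, serialization."""

import itertools

import numpy as np
import pytest

from reachtrack.tracker import (CascadeTracker, TrackConfig, TrackResult,
                                apply_corrections, cluster_modes,
                                pose_indexed_features, select_modes_dp,
                                smooth_track)


def brute_force_cost(modes, lam, assignment):
    cost = 0.0
    prev = None
    for mlist, a in zip(modes, assignment):
        pos, wgt = mlist[a]
        total = sum(w for _, w in mlist)
        cost += -np.log(max(wgt / total, 1e-12))
        if prev is not None:
            cost += lam * float(((np.asarray(pos) - prev) ** 2).sum())
        prev = np.asarray(pos)
    return cost


def brute_force_best(modes, lam, pinned=None):
    pinned = pinned or {}
    best = None
    best_assign = None
    for assign in itertools.product(*[range(len(m)) for m in modes]):
        if any(assign[t] != m for t, m in pinned.items()):
            continue
        c = brute_force_cost(modes, lam, assign)
        if best is None or c < best - 1e-12:
            best, best_assign = c, assign
    return best, best_assign


def random_frame_modes(rng, max_modes=4):
    k = rng.integers(1, max_modes + 1)
    return [(rng.uniform(0, 100, 2), float(rng.integers(1, 20))) for _ in range(k)]


def random_instance(rng, max_frames=6, max_modes=4):
    n = rng.integers(2, max_frames + 1)
    return [random_frame_modes(rng, max_modes) for _ in range(n)]


class TestPoseIndexedFeatures:
    def test_constant_image_gives_zero_features(self):
        img = np.full((50, 60), 37.0)
        defs = [((2, 3), (-4, 1)), ((0, 0), (5, 5))]
        np.testing.assert_allclose(pose_indexed_features(img, (30, 25), defs), 0.0)

    def test_direct_intensity_difference(self):
        img = np.zeros((40, 40))
        img[22, 13] = 10.0   # pose + offsetA = (13, 22)
        img[18, 9] = 3.0     # pose + offsetB = (9, 18)
        feats = pose_indexed_features(img, (10, 20), [((3, 2), (-1, -2))])
        assert feats[0] == pytest.approx(7.0)

    def test_empty_feature_defs_error(self):
        with pytest.raises(ValueError):
            pose_indexed_features(np.zeros((10, 10)), (5, 5), [])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        defs = [((int(a), int(b)), (int(c), int(d)))
                for a, b, c, d in rng.integers(-8, 9, (20, 4))]
        for _ in range(10):
            img = rng.normal(size=(80, 80))
            shifted = np.roll(np.roll(img, 5, axis=0), 5, axis=1)
            f1 = pose_indexed_features(img, (40, 40), defs)
            f2 = pose_indexed_features(shifted, (45, 45), defs)
            np.testing.assert_allclose(f1, f2)


class TestTraining:
    def test_requires_ten_labeled_frames(self):
        imgs = [np.zeros((20, 20))] * 5
        with pytest.raises(ValueError, match="10 labeled"):
            CascadeTracker(n_stages=2).fit(imgs, np.full((5, 2), 10.0))

    def test_degenerate_labels_warn(self):
        rng = np.random.default_rng(1)
        imgs = [rng.normal(size=(30, 30)) for _ in range(12)]
        with pytest.warns(UserWarning, match="identical"):
            CascadeTracker(n_stages=2, n_ferns=5, n_candidate_features=20,
                           n_selected_features=10, random_state=0).fit(
                imgs, np.full((12, 2), 15.0))

    def test_median_stage_error_non_increasing(self, small_tracker):
        hist = small_tracker.training_history_
        assert np.all(np.diff(hist) <= 0.5)

    def test_low_final_error_on_clean_blobs(self, small_tracker):
        assert small_tracker.training_history_[-1] < 2.0


class TestTracking:
    def test_held_out_frames_tracked_within_3px(self, small_tracker, held_out_frames):
        frames, gt = held_out_frames
        res = small_tracker.track_video(frames, TrackConfig(), seed=11)
        err = np.linalg.norm(res.positions() - gt, axis=1)
        assert np.median(err) <= 3.0

    def test_pure_noise_frame_has_diffuse_modes(self, small_tracker):
        rng = np.random.default_rng(5)
        noise = rng.uniform(0, 255, size=(100, 120)).astype(np.float32)
        modes = small_tracker.track_frame(noise, TrackConfig(), seed=0)
        top_fraction = modes[0][1] / sum(w for _, w in modes)
        assert top_fraction < TrackConfig().error_spread_threshold

    def test_track_video_deterministic_under_seed(self, small_tracker, held_out_frames):
        frames, _ = held_out_frames
        r1 = small_tracker.track_video(frames[:10], TrackConfig(), seed=3)
        r2 = small_tracker.track_video(frames[:10], TrackConfig(), seed=3)
        np.testing.assert_array_equal(r1.positions(), r2.positions())
        assert r1.flagged == r2.flagged


class TestModeClustering:
    def test_two_well_separated_clusters(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal([20, 20], 0.5, (30, 2)),
                         rng.normal([80, 70], 0.5, (10, 2))])
        modes = cluster_modes(pts, bandwidth=5.0)
        assert len(modes) == 2
        assert modes[0][1] == 30
        np.testing.assert_allclose(modes[0][0], [20, 20], atol=0.5)


class TestSmoothing:
    def test_lambda_zero_reduces_to_per_frame_top_mode(self):
        rng = np.random.default_rng(3)
        modes = [random_frame_modes(rng) for _ in range(8)]
        sel = select_modes_dp(modes, 0.0)
        expected = [int(np.argmax([w for _, w in m])) for m in modes]
        for s, e, m in zip(sel, expected, modes):
            assert m[s][1] == m[e][1]  # equal weight on ties

    def test_constant_candidates_give_constant_track_no_flags(self):
        mode = [(np.array([50.0, 40.0]), 45.0), (np.array([10.0, 10.0]), 5.0)]
        res = smooth_track([list(mode) for _ in range(10)], TrackConfig())
        assert res.flagged == []
        np.testing.assert_allclose(res.positions(),
                                   np.tile([50.0, 40.0], (10, 1)))

    def test_displaced_middle_frame_resolved_or_flagged(self):
        # neighbors agree at (50, 50); middle frame's top mode jumped 50 px
        agree = [(np.array([50.0, 50.0]), 40.0), (np.array([90.0, 20.0]), 10.0)]
        displaced = [(np.array([100.0, 50.0]), 30.0), (np.array([50.0, 50.0]), 20.0)]
        res = smooth_track([agree, displaced, agree], TrackConfig())
        picked = res.positions()[1]
        consistent = np.allclose(picked, [50.0, 50.0])
        assert consistent or 1 in res.flagged
        best, assign = brute_force_best([agree, displaced, agree],
                                        TrackConfig().smoothness_weight)
        sel = select_modes_dp([agree, displaced, agree],
                              TrackConfig().smoothness_weight)
        assert brute_force_cost([agree, displaced, agree],
                                TrackConfig().smoothness_weight, sel) \
            == pytest.approx(best)

    @pytest.mark.parametrize("lam", [0.0, 0.01, 0.5])
    def test_dp_matches_exhaustive_enumeration(self, lam):
        rng = np.random.default_rng(4)
        for _ in range(200):
            modes = random_instance(rng)
            sel = select_modes_dp(modes, lam)
            best, _ = brute_force_best(modes, lam)
            assert brute_force_cost(modes, lam, sel) == pytest.approx(best)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            smooth_track([], TrackConfig())


class TestCorrections:
    def _result(self, rng, n=6):
        modes = [random_frame_modes(rng) for _ in range(n)]
        return smooth_track(modes, TrackConfig())

    def test_empty_corrections_identity(self):
        res = self._result(np.random.default_rng(6))
        out = apply_corrections(res, {}, TrackConfig())
        np.testing.assert_array_equal(out.positions(), res.positions())

    def test_pinning_flagged_frame_removes_flag(self):
        low = [(np.array([50.0, 50.0]), 1.0), (np.array([20.0, 20.0]), 1.0),
               (np.array([80.0, 80.0]), 1.0)]  # three-way split: low confidence
        good = [(np.array([50.0, 50.0]), 50.0)]
        res = smooth_track([good, low, good], TrackConfig())
        assert 1 in res.flagged
        out = apply_corrections(res, {1: (50.0, 50.0)}, TrackConfig())
        assert 1 not in out.flagged
        assert out.estimates[1].confidence == 1.0

    def test_pin_matches_exhaustive_resolve(self):
        rng = np.random.default_rng(7)
        lam = TrackConfig().smoothness_weight
        for _ in range(50):
            modes = random_instance(rng, 5, 3)
            res = smooth_track(modes, TrackConfig())
            t_pin = len(modes) // 2
            xy = np.array([55.0, 45.0])
            out = apply_corrections(res, {t_pin: tuple(xy)}, TrackConfig())
            pin_modes = [list(m) for m in modes]
            total = sum(w for _, w in pin_modes[t_pin])
            pin_modes[t_pin] = pin_modes[t_pin] + [(xy, total)]
            best, _ = brute_force_best(pin_modes, lam,
                                       pinned={t_pin: len(pin_modes[t_pin]) - 1})
            sel = [np.argmin([np.sum((np.asarray(p) - out.positions()[t]) ** 2)
                              for p, _ in pin_modes[t]])
                   for t in range(len(modes))]
            assert brute_force_cost(pin_modes, lam, sel) == pytest.approx(best)

    def test_out_of_range_correction_error(self):
        res = self._result(np.random.default_rng(8))
        with pytest.raises(ValueError, match="out of range"):
            apply_corrections(res, {99: (1.0, 1.0)}, TrackConfig())


class TestSerialization:
    def test_json_roundtrip_preserves_tracking(self, small_tracker, held_out_frames,
                                               tmp_path):
        frames, _ = held_out_frames
        path = tmp_path / "model.json"
        small_tracker.to_json(path)
        loaded = CascadeTracker.from_json(path)
        m1 = small_tracker.track_frame(frames[0], TrackConfig(), seed=1)
        m2 = loaded.track_frame(frames[0], TrackConfig(), seed=1)
        np.testing.assert_allclose(m1[0][0], m2[0][0])
        assert m1[0][1] == m2[0][1]

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "bogus.json"
        p.write_text('{"format": "other"}')
        with pytest.raises(ValueError):
            CascadeTracker.from_json(p)
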