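import itertools

import numpy as np
import pytest

from standtrack.geometry import Box, Measurement, box_to_measurement, iou
from standtrack.tracking import (
    MultiObjectTracker,
    TrackerConfig,
    associate,
    init_track,
    kf_predict,
    kf_update,
    step_tracks,
)

from conftest import random_box

CFG = TrackerConfig()


def make_state(u=0.0, v=0.0, s=100.0, r=1.0, du=0.0, dv=0.0, ds=0.0, dr=0.0):
    return np.array([u, v, s, r, du, dv, ds, dr], dtype=float)


def assert_psd_symmetric(p, tol=1e-9):
    assert np.allclose(p, p.T, atol=tol)
    assert np.linalg.eigvalsh(p).min() >= -tol


class TestKalmanPredict:
    def test_constant_velocity_propagation(self):
        x, p = kf_predict(make_state(0, 0, 100, 1, 5, 10, 0, 0), np.eye(8), CFG.process_noise())
        assert np.allclose(x[:4], [5, 10, 100, 1])
        assert np.allclose(x[4:], [5, 10, 0, 0])

    def test_zero_rates_identity(self):
        x0 = make_state(3, 4, 50, 2)
        x, _ = kf_predict(x0, np.eye(8), CFG.process_noise())
        assert np.allclose(x, x0)

    def test_two_predicts_closed_form(self):
        x = make_state(0, 0, 100, 1, 5, 10, 2, 0.01)
        p = np.eye(8)
        q = CFG.process_noise()
        for _ in range(2):
            x, p = kf_predict(x, p, q)
        assert np.allclose(x[:4], [10, 20, 104, 1.02])
        assert np.allclose(x[4:], [5, 10, 2, 0.01])

    def test_covariance_inflates(self):
        _, p = kf_predict(make_state(), np.eye(8), CFG.process_noise())
        assert np.trace(p) > 8.0
        assert_psd_symmetric(p)


class TestKalmanUpdate:
    def test_zero_measurement_noise_limit(self):
        z = Measurement(u=7.0, v=8.0, s=120.0, r=1.2)
        x, p = kf_update(make_state(), np.eye(8), z, np.zeros((4, 4)))
        assert np.allclose(x[:4], [7, 8, 120, 1.2])
        assert_psd_symmetric(p)

    def test_certain_prior_limit(self):
        x0 = make_state(1, 2, 100, 1)
        z = Measurement(u=50.0, v=60.0, s=200.0, r=2.0)
        x, _ = kf_update(x0, np.zeros((8, 8)), z, np.eye(4))
        assert np.allclose(x, x0)

    def test_scalar_gain_half(self):
        # prior variance 1 on u, measurement variance 1 -> posterior mean is
        # the average of prior and measurement (1-D Kalman gain 0.5)
        x0 = make_state(u=0.0, v=0.0, s=100.0, r=1.0)
        p0 = np.diag([1.0, 0, 0, 0, 0, 0, 0, 0]) + 1e-12 * np.eye(8)
        z = Measurement(u=10.0, v=1e-9, s=100.0, r=1.0)
        x, _ = kf_update(x0, p0, z, np.eye(4))
        assert x[0] == pytest.approx(5.0, abs=1e-6)

    def test_posterior_trace_not_larger(self, rng):
        x = make_state(10, 10)
        p = np.eye(8) * 5.0
        z = Measurement(u=12.0, v=9.0, s=110.0, r=1.1)
        _, p_post = kf_update(x, p, z, CFG.measurement_noise())
        assert np.trace(p_post) <= np.trace(p) + 1e-12
        assert_psd_symmetric(p_post)

    def test_random_sequences_stay_psd(self, rng):
        # filter consistency over long random predict/update interleavings
        x = make_state(50, 50, 400, 1)
        p = CFG.initial_covariance()
        q, r = CFG.process_noise(), CFG.measurement_noise()
        for _ in range(500):
            x, p = kf_predict(x, p, q)
            if rng.random() < 0.7:
                z = Measurement(
                    u=float(x[0] + rng.normal(0, 2)),
                    v=float(x[1] + rng.normal(0, 2)),
                    s=float(abs(x[2]) + 1 + rng.normal(0, 5)),
                    r=float(np.clip(x[3] + rng.normal(0, 0.05), 0.1, 5)),
                )
                x, p = kf_update(x, p, z, r)
            assert_psd_symmetric(p, tol=1e-6)


class TestInitTrack:
    def test_state_from_box(self):
        t = init_track(Box(90, 30, 110, 70), 1)
        assert np.allclose(t.state, [100, 50, 800, 0.5, 0, 0, 0, 0])
        assert t.counted is False
        assert t.time_since_update == 0

    def test_distinct_ids(self):
        t1 = init_track(Box(0, 0, 10, 10), 1)
        t2 = init_track(Box(0, 0, 10, 10), 2)
        assert t1.id != t2.id

    def test_zero_initial_velocity(self):
        t = init_track(Box(0, 0, 10, 10), 1)
        x, _ = kf_predict(t.state, t.covariance, np.zeros((8, 8)))
        assert np.allclose(x[:2], t.state[:2])

    def test_rate_variances_large(self):
        t = init_track(Box(0, 0, 10, 10), 1)
        diag = np.diag(t.covariance)
        assert (diag[4:] > 100 * diag[:4]).all()


def brute_force_best_total(iou_matrix):
    """Max total IoU over one-to-one assignments, by permutation enumeration."""
    n_trk, n_det = iou_matrix.shape
    best = 0.0
    if n_trk <= n_det:
        for perm in itertools.permutations(range(n_det), n_trk):
            best = max(best, sum(iou_matrix[i, j] for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(n_trk), n_det):
            best = max(best, sum(iou_matrix[i, j] for j, i in enumerate(perm)))
    return best


class TestAssociate:
    def test_single_match(self):
        trk = Box(0, 0, 10, 10)
        det = Box(1, 0, 11, 10)  # IoU 9/11 ≈ 0.82
        res = associate([det], [(7, trk)], 0.3)
        assert res.matches == ((7, 0),)
        assert res.unmatched_detections == ()
        assert res.unmatched_tracks == ()

    def test_gate_rejection(self):
        trk = Box(0, 0, 10, 10)
        det = Box(9, 9, 19, 19)  # IoU ≈ 0.005
        res = associate([det], [(7, trk)], 0.3)
        assert res.matches == ()
        assert res.unmatched_detections == (0,)
        assert res.unmatched_tracks == (7,)

    def test_empty_inputs(self):
        res = associate([], [], 0.3)
        assert res.matches == () and res.unmatched_detections == ()
        res = associate([Box(0, 0, 1, 1)], [], 0.3)
        assert res.unmatched_detections == (0,)

    def test_3x3_matches_brute_force(self, rng):
        for _ in range(50):
            tracks = [(i + 1, random_box(rng, hi=60)) for i in range(3)]
            dets = [random_box(rng, hi=60) for _ in range(3)]
            mat = np.array([[iou(tb, d) for d in dets] for _, tb in tracks])
            res = associate(dets, tracks, 0.0)
            total = sum(mat[tid - 1, j] for tid, j in res.matches)
            assert total == pytest.approx(brute_force_best_total(mat), abs=1e-9)

    def test_partition_invariant(self, rng):
        for _ in range(100):
            n_trk = int(rng.integers(0, 7))
            n_det = int(rng.integers(0, 7))
            tracks = [(i + 1, random_box(rng, hi=80)) for i in range(n_trk)]
            dets = [random_box(rng, hi=80) for _ in range(n_det)]
            thr = float(rng.uniform(0, 1))
            res = associate(dets, tracks, thr)
            matched_t = [tid for tid, _ in res.matches]
            matched_d = [j for _, j in res.matches]
            assert sorted(matched_t + list(res.unmatched_tracks)) == sorted(
                t for t, _ in tracks
            )
            assert sorted(matched_d + list(res.unmatched_detections)) == list(
                range(n_det)
            )
            for tid, j in res.matches:
                tbox = dict(tracks)[tid]
                assert iou(tbox, dets[j]) >= thr


class TestStepTracks:
    def test_cold_start(self):
        tracks, res = step_tracks(
            [], [Box(0, 0, 10, 10), Box(50, 50, 60, 60)], CFG
        )
        assert sorted(t.id for t in tracks) == [1, 2]
        assert res.unmatched_detections == (0, 1)

    def test_max_age_deletion(self):
        # paper setting: max_age=2 -> deleted on the 3rd consecutive miss
        cfg = TrackerConfig(max_age=2)
        tracks, _ = step_tracks([], [Box(0, 0, 10, 10)], cfg)
        for frame in range(3):
            tracks, _ = step_tracks(tracks, [], cfg)
            if frame < 2:
                assert len(tracks) == 1, f"should coast at miss {frame + 1}"
        assert tracks == []

    def test_identity_preserved_noise_free(self):
        # constant-velocity detections over 10 frames -> one id throughout
        tracker = MultiObjectTracker()
        seen_ids = set()
        for frame in range(10):
            y = 10.0 + 8.0 * frame
            tracker.step([Box(45, y, 75, y + 30)])
            seen_ids.update(t.id for t in tracker.tracks)
        assert seen_ids == {1}

    def test_track_count_conservation(self, rng):
        tracker = MultiObjectTracker()
        for _ in range(60):
            dets = [random_box(rng, hi=150) for _ in range(int(rng.integers(0, 5)))]
            tracker.step(dets)
            assert tracker.created - tracker.deleted == len(tracker.tracks)

    def test_ids_not_reused_after_extinction(self):
        tracker = MultiObjectTracker(TrackerConfig(max_age=0))
        tracker.step([Box(0, 0, 10, 10)])
        tracker.step([])  # track dies
        assert tracker.tracks == []
        tracker.step([Box(100, 100, 110, 110)])
        assert tracker.tracks[0].id == 2

    def test_velocity_recovery(self):
        # filtered velocity approaches the true per-frame displacement
        rng = np.random.default_rng(7)
        du_true, dv_true = 1.5, 12.0
        tracker = MultiObjectTracker()
        for frame in range(30):
            cx = 100 + du_true * frame + rng.normal(0, 1.0)
            cy = 50 + dv_true * frame + rng.normal(0, 1.0)
            tracker.step([Box(cx - 20, cy - 20, cx + 20, cy + 20)])
        (track,) = tracker.tracks
        du, dv = track.state[4], track.state[5]
        se_u = np.sqrt(track.covariance[4, 4])
        se_v = np.sqrt(track.covariance[5, 5])
        assert abs(du - du_true) < 3 * se_u
        assert abs(dv - dv_true) < 3 * se_v

    def test_counted_flag_monotone(self):
        t = init_track(Box(0, 0, 10, 10), 1)
        assert not t.counted
        t.counted = True
        # lifecycle code never resets it; step a frame and check
        tracks, _ = step_tracks([t], [Box(0, 0, 10, 10)], CFG)
        assert tracks[0].counted
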