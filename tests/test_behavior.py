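import numpy as np
import pytest

from thermophase import errors
from thermophase.behavior import (
    WormTrack,
    angle_between,
    curving_rate,
    detect_events,
    detect_omega_turns,
    detect_reversals,
    load_tracks,
    moving_direction,
    moving_vector,
    curving_profile,
    section_distribution,
    score_event_recovery,
    tracks_to_frame,
)
from thermophase.synth import TrackPolicy, simulate_tracks

FR = 13.5
DT = 1.0 / FR


def build_track(turn_rate_deg_s, body_length_um, speed=100.0, animal_id="w0"):
    """Integrate per-frame turn rates (deg/s) into a track; straight body."""
    n = turn_rate_deg_s.size
    heading = np.cumsum(np.deg2rad(turn_rate_deg_s) * DT)
    pos = np.zeros((n, 2))
    step = speed * DT * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    pos[1:] = np.cumsum(step[:-1], axis=0)
    offsets = np.arange(11)[None, :] * (body_length_um / 10.0)[:, None]
    direction = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    segments = pos[:, None, :] - offsets[:, :, None] * direction[:, None, :]
    return WormTrack(animal_id, np.arange(n), np.arange(n) * DT, pos, segments,
                     frame_rate=FR)


def straight_track(n=810, speed=100.0, length=1000.0, jitter_seed=0):
    rng = np.random.default_rng(jitter_seed)
    turns = np.zeros(n)
    lengths = length * (1.0 + rng.normal(0.0, 0.01, n))
    return build_track(turns, lengths, speed=speed)


class TestKinematics:
    def test_stationary_worm(self):
        tr = build_track(np.zeros(50), np.full(50, 1000.0), speed=0.0)
        r = moving_vector(tr)
        assert np.all(np.isnan(r[:14]))
        np.testing.assert_allclose(r[14:], 0.0)

    def test_uniform_motion(self):
        tr = straight_track(100)
        r = moving_vector(tr)
        np.testing.assert_allclose(r[14:, 0], 100.0 * 14 * DT, rtol=1e-9)
        np.testing.assert_allclose(r[14:, 1], 0.0, atol=1e-9)

    def test_lag_is_14_frames(self):
        tr = straight_track(100)
        r = moving_vector(tr, lag=1.0)
        assert np.isnan(r[:14]).all() and np.isfinite(r[14:]).all()

    @pytest.mark.parametrize(
        "vec, expected",
        [((1.0, 0.0), 0.0), ((-1.0, 0.0), 180.0), ((0.0, 1.0), 90.0),
         ((0.0, -1.0), 90.0), ((1.0, 1.0), 45.0)],
    )
    def test_moving_direction_folds(self, vec, expected):
        theta = moving_direction(np.array([vec]))
        assert theta[0] == pytest.approx(expected)

    def test_zero_vector_undefined(self):
        assert np.isnan(moving_direction(np.array([[0.0, 0.0]]))[0])

    @pytest.mark.parametrize(
        "prev, now, expected",
        [((1, 0), (1, 0), 0.0), ((1, 0), (0, 1), 90.0), ((1, 0), (-1, 0), 180.0)],
    )
    def test_angle_between(self, prev, now, expected):
        assert angle_between(np.array(prev, float), np.array(now, float)) == (
            pytest.approx(expected)
        )

    def test_angle_between_zero_vector(self):
        assert np.isnan(angle_between(np.zeros(2), np.ones(2)))

    def test_curving_rate_on_arc(self):
        # constant 30 deg/s turning: curving rate ~30 deg/s
        tr = build_track(np.full(400, 30.0), np.full(400, 1000.0))
        phi = curving_rate(tr)
        assert np.nanmedian(phi) == pytest.approx(30.0, rel=0.05)


class TestDetectors:
    @staticmethod
    def injected_track(shrink=0.6, turn=120.0, kind="omega", seed=0):
        n = 810  # 60 s
        rng = np.random.default_rng(seed)
        turns = np.zeros(n)
        lengths = 1000.0 * (1.0 + rng.normal(0.0, 0.01, n))
        s, e = 405, 405 + int(3 * FR)  # 3-s episode at t = 30 s
        if kind == "omega":
            turns[s:e] = turn
            lengths[s:e] *= shrink
        elif kind == "shrink_only":
            lengths[s:e] *= shrink
        elif kind == "turn_only":
            turns[s:e] = turn
        return build_track(turns, lengths), (s, e - 1)

    def test_omega_injection_recovered(self):
        tr, (s, e) = self.injected_track()
        events = detect_omega_turns(tr)
        assert len(events) == 1
        ds, de = events[0]
        assert s - 14 <= ds and de <= e + 14

    def test_shrink_without_curving_ignored(self):
        tr, _ = self.injected_track(kind="shrink_only")
        assert detect_omega_turns(tr) == []

    def test_curving_without_shrink_ignored(self):
        tr, _ = self.injected_track(kind="turn_only")
        assert detect_omega_turns(tr) == []

    def test_zero_length_variance_warns(self):
        tr = build_track(np.zeros(810), np.full(810, 1000.0))
        with pytest.warns(UserWarning):
            assert detect_omega_turns(tr) == []

    def test_reversal_flip_detected(self):
        n = 810
        turns = np.zeros(n)
        turns[405] = 180.0 / DT  # instantaneous 180-degree flip
        tr = build_track(turns, np.full(n, 1000.0))
        events = detect_reversals(tr)
        assert len(events) == 1
        ds, de = events[0]
        assert abs(ds - 405) <= 16

    def test_smooth_arc_not_reversal(self):
        tr = build_track(np.full(600, 30.0), np.full(600, 1000.0))
        assert detect_reversals(tr) == []

    def test_sub_threshold_flip_ignored(self):
        # a 100-degree direction change never reaches the 150 deg/s rule
        n = 810
        turns = np.zeros(n)
        turns[405] = 100.0 / DT
        tr = build_track(turns, np.full(n, 1000.0))
        assert detect_reversals(tr) == []

    def test_short_track_rejected(self):
        tr = straight_track(100)  # ~7 s, below the 30-s minimum
        with pytest.raises(errors.LengthError):
            detect_omega_turns(tr)


class TestInvariances:
    def test_reflection_about_gradient_axis(self):
        tr, _ = TestDetectors.injected_track()
        mirrored = WormTrack(
            tr.animal_id, tr.frame, tr.time,
            tr.centroid * np.array([1.0, -1.0]),
            tr.segments * np.array([1.0, -1.0]),
            frame_rate=FR,
        )
        phi_a, phi_b = curving_rate(tr), curving_rate(mirrored)
        np.testing.assert_allclose(phi_a[14:], phi_b[14:], atol=1e-9)
        th_a = moving_direction(moving_vector(tr))
        th_b = moving_direction(moving_vector(mirrored))
        np.testing.assert_allclose(th_a[14:], th_b[14:], atol=1e-9)
        assert detect_events(tr).omega_turns == detect_events(mirrored).omega_turns
        assert detect_events(tr).reversals == detect_events(mirrored).reversals

    def test_pixel_to_micron_scaling(self):
        tr, _ = TestDetectors.injected_track()
        scaled = WormTrack(
            tr.animal_id, tr.frame, tr.time,
            tr.centroid * 33.2, tr.segments * 33.2, frame_rate=FR,
        )
        np.testing.assert_allclose(
            curving_rate(tr)[14:], curving_rate(scaled)[14:], atol=1e-9
        )
        assert detect_events(tr).omega_turns == detect_events(scaled).omega_turns


class TestPlateSummaries:
    def test_point_mass_distribution(self):
        tr = build_track(np.zeros(50), np.full(50, 1000.0), speed=0.0)
        dist = section_distribution([tr], n_sections=4, time_bin=10.0,
                                    x_extent=(-1000.0, 1000.0))
        row = dist.iloc[0].to_numpy()
        # the stationary worm sits at x = 0, boundary of sections 2 and 3
        assert row.sum() == pytest.approx(1.0)
        assert row.max() == pytest.approx(1.0)

    def test_uniform_scatter(self):
        rng = np.random.default_rng(0)
        n = 1000
        pos = np.stack([rng.uniform(-1000, 1000, n), np.zeros(n)], axis=1)
        seg = pos[:, None, :] + np.zeros((n, 11, 2))
        seg += np.linspace(0, 100, 11)[None, :, None]
        tr = WormTrack("u", np.arange(n), np.arange(n) * DT, pos, seg, FR)
        dist = section_distribution([tr], n_sections=4, time_bin=1000.0,
                                    x_extent=(-1000.0, 1000.0))
        np.testing.assert_allclose(dist.iloc[0], 0.25, atol=0.05)

    def test_rows_sum_to_one(self):
        tracks, _ = simulate_tracks(n_worms=3, duration_s=60.0, seed=0)
        dist = section_distribution(tracks, n_sections=8, time_bin=20.0)
        sums = dist.sum(axis=1, skipna=False).to_numpy()
        finite = np.isfinite(sums)
        np.testing.assert_allclose(sums[finite], 1.0)

    def test_curving_profile_constant_policy(self):
        tr = build_track(np.full(2000, 20.0), np.full(2000, 1000.0))
        prof = curving_profile([tr], window=(0.0, 200.0), direction_bin_deg=45.0)
        vals = prof.dropna().to_numpy()
        assert vals.size > 0
        np.testing.assert_allclose(vals, 20.0, rtol=0.1)

    def test_curving_profile_empty_window(self):
        tr = straight_track(200)
        prof = curving_profile([tr], window=(1e6, 2e6))
        assert prof.isna().all()


class TestEventScoring:
    def test_perfect_and_empty(self):
        assert score_event_recovery([(10, 20)], [(12, 18)]) == (1.0, 1.0)
        assert score_event_recovery([], []) == (1.0, 1.0)
        assert score_event_recovery([(0, 5)], []) == (0.0, 1.0)
        p, r = score_event_recovery([], [(0, 5)])
        assert p == 1.0 and r == 0.0

    def test_detector_precision_recall_on_injected_events(self):
        """Injection-recovery: both detectors >= 0.9 precision and recall."""
        tracks, truth = simulate_tracks(n_worms=20, duration_s=600.0, seed=42)
        for kind in ("omega_turns", "reversals"):
            tp = fp = fn = 0
            for tr in tracks:
                detected = getattr(detect_events(tr), kind)
                true_events = truth[tr.animal_id][kind]
                claimed = [False] * len(true_events)
                hits = 0
                for ds, de in detected:
                    for i, (ts, te) in enumerate(true_events):
                        if not claimed[i] and ds <= te + 14 and de >= ts - 14:
                            claimed[i] = True
                            hits += 1
                            break
                tp += hits
                fp += len(detected) - hits
                fn += len(true_events) - hits
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
            assert precision >= 0.9, (kind, precision)
            assert recall >= 0.9, (kind, recall)


class TestTrackIO:
    def test_round_trip(self, tmp_path):
        tracks, _ = simulate_tracks(n_worms=2, duration_s=30.0, seed=5)
        path = tmp_path / "tracks.tsv"
        tracks_to_frame(tracks).to_csv(path, sep="\t", index=False)
        loaded = load_tracks(path)
        assert len(loaded) == 2
        np.testing.assert_allclose(loaded[0].centroid, tracks[0].centroid)
        np.testing.assert_allclose(loaded[0].segments, tracks[0].segments)

    def test_missing_column(self, tmp_path):
        tracks, _ = simulate_tracks(n_worms=1, duration_s=30.0, seed=5)
        df = tracks_to_frame(tracks).drop(columns=["cx_um"])
        path = tmp_path / "tracks.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(errors.SchemaError):
            load_tracks(path)
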