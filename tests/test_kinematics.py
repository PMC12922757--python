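import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from constrictaxis.device import DeviceGeometry
from constrictaxis.errors import FormatError, InvalidParameterError
from constrictaxis.kinematics import (
    Track,
    TrackSet,
    eccentricity_timecourse,
    filter_tracks,
    forward_migration_index,
    peri_summary,
    read_tracks,
    split_at_constriction,
    track_directionality,
    track_speed,
    write_tracks,
)
from constrictaxis.synthetic_data import PhenotypeParams, simulate_cohort


def make_track(xs, ys=None, dt=60.0, track_id=0, **attachments):
    xs = np.asarray(xs, dtype=float)
    ys = np.zeros_like(xs) if ys is None else np.asarray(ys, dtype=float)
    frames = np.arange(len(xs))
    return Track(
        track_id=track_id,
        frames=frames,
        times=frames * dt,
        x=xs,
        y=ys,
        attachments={k: np.asarray(v, dtype=float) for k, v in attachments.items()},
    )


class TestTrackValidation:
    def test_needs_two_points(self):
        with pytest.raises(InvalidParameterError):
            make_track([1.0])

    def test_times_strictly_increasing(self):
        with pytest.raises(InvalidParameterError):
            Track(0, np.array([0, 1]), np.array([5.0, 5.0]),
                  np.array([0.0, 1.0]), np.array([0.0, 0.0]))

    def test_attachment_length(self):
        with pytest.raises(InvalidParameterError):
            make_track([0, 1, 2], intensity=[1.0])


class TestReadWrite:
    def test_two_row_file(self, tmp_path):
        p = tmp_path / "spots.csv"
        p.write_text(
            "TRACK_ID,FRAME,POSITION_T,POSITION_X,POSITION_Y\n"
            "0,0,0,1.0,2.0\n0,1,30,3.0,4.0\n"
        )
        ts = read_tracks(p, frame_interval=30.0)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 2

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "spots.csv"
        p.write_text("TRACK_ID,FRAME,POSITION_X\n0,0,1.0\n")
        with pytest.raises(FormatError, match="POSITION_Y"):
            read_tracks(p)

    def test_duplicate_pair_named(self, tmp_path):
        p = tmp_path / "spots.csv"
        p.write_text(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y\n"
            "7,3,1.0,2.0\n7,3,1.5,2.5\n"
        )
        with pytest.raises(FormatError, match=r"\(7, 3\)"):
            read_tracks(p)

    def test_malformed_rows_counted(self, tmp_path):
        p = tmp_path / "spots.csv"
        p.write_text(
            "TRACK_ID,FRAME,POSITION_X,POSITION_Y\n"
            "0,0,1.0,2.0\nLabel,(um),(um),(um)\n0,1,3.0,4.0\n"
        )
        ts = read_tracks(p)
        assert ts.provenance["malformed_rows"] == 1
        assert len(ts.tracks[0]) == 2

    def test_simulator_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "spots.csv"
        write_tracks(small_cohort.tracks, path)
        back = read_tracks(path, frame_interval=30.0)
        orig = {t.track_id: t for t in small_cohort.tracks}
        assert sorted(orig) == sorted(t.track_id for t in back)
        for t in back:
            o = orig[t.track_id]
            assert np.allclose(t.x, o.x, atol=1e-6)
            assert np.allclose(t.y, o.y, atol=1e-6)
            assert np.allclose(
                t.attachments["intensity"], o.attachments["intensity"], atol=1e-6
            )


class TestFilter:
    def _ts(self, finals):
        tracks = [
            make_track([0.0, f / 2, f], track_id=i) for i, f in enumerate(finals)
        ]
        return TrackSet(tracks=tuple(tracks), frame_interval=60.0)

    def test_hand_computed_subset(self):
        ts = self._ts([150.0, 99.9, 100.0, 20.0, 300.0])
        kept = filter_tracks(ts, min_final_x=100.0)
        finals = sorted(t.x[-1] for t in kept)
        assert finals == [100.0, 150.0, 300.0]
        log = kept.provenance["filter_log"][0]
        assert log["n_excluded"] == 2

    def test_identity_on_long_tracks(self):
        ts = self._ts([200.0, 250.0, 300.0])
        assert len(filter_tracks(ts)) == 3

    def test_idempotent(self):
        ts = self._ts([150.0, 50.0, 120.0])
        once = filter_tracks(ts)
        twice = filter_tracks(once)
        assert [t.track_id for t in once] == [t.track_id for t in twice]


class TestSpeedDirectionality:
    def test_straight_speed(self):
        t = make_track([0.0, 30.0], dt=60.0)
        assert track_speed(t) == pytest.approx(30.0)

    def test_stationary_speed(self):
        t = make_track([5.0, 5.0, 5.0])
        assert track_speed(t) == 0.0

    def test_zigzag_speed(self):
        # (0,0) -> (10,10) -> (20,0) over 2 min: 2*sqrt(200)/2 um/min
        t = make_track([0.0, 10.0, 20.0], [0.0, 10.0, 0.0], dt=60.0)
        assert track_speed(t) == pytest.approx(np.sqrt(200.0), rel=1e-9)
        assert track_speed(t) == pytest.approx(14.142, abs=1e-3)

    def test_straight_directionality(self):
        t = make_track([0.0, 10.0, 25.0, 40.0])
        assert track_directionality(t) == pytest.approx(1.0)

    def test_closed_loop_directionality(self):
        t = make_track([0.0, 10.0, 10.0, 0.0], [0.0, 0.0, 10.0, 0.0])
        assert track_directionality(t) == pytest.approx(0.0)

    def test_zigzag_directionality(self):
        t = make_track([0.0, 10.0, 20.0], [0.0, 10.0, 0.0])
        assert track_directionality(t) == pytest.approx(20.0 / 28.284, abs=1e-4)
        assert track_directionality(t) == pytest.approx(0.7071, abs=1e-4)

    def test_stationary_directionality_warns(self):
        t = make_track([5.0, 5.0])
        with pytest.warns(UserWarning):
            assert track_directionality(t) == 0.0

    def test_fmi_negative_for_backward(self):
        t = make_track([50.0, 20.0])
        assert forward_migration_index(t) == pytest.approx(-1.0)

    @given(
        dx=st.floats(-500, 500), dy=st.floats(-500, 500),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_and_time_invariance(self, dx, dy, scale):
        rng = np.random.default_rng(42)
        xs = np.cumsum(rng.normal(2, 1, 20))
        ys = np.cumsum(rng.normal(0, 1, 20))
        t1 = make_track(xs, ys)
        t2 = make_track(xs + dx, ys + dy)  # translation
        assert track_speed(t1) == pytest.approx(track_speed(t2), rel=1e-9)
        assert track_directionality(t1) == pytest.approx(
            track_directionality(t2), rel=1e-9
        )
        t3 = make_track(xs, ys, dt=60.0 * scale)  # uniform time rescaling
        assert track_directionality(t1) == pytest.approx(
            track_directionality(t3), rel=1e-9
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_directionality_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        t = make_track(rng.normal(0, 50, n), rng.normal(0, 50, n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = track_directionality(t)
        assert 0.0 <= d <= 1.0


def brute_force_split(x, cx, ex):
    """Frame-by-frame scan oracle for first-entry/first-exit splitting."""
    entry = None
    for i, xi in enumerate(x):
        if xi >= cx:
            entry = i
            break
    if entry is None:
        return list(range(len(x))), [], []
    exit_i = None
    for i in range(entry, len(x)):
        if x[i] > ex:
            exit_i = i
            break
    if exit_i is None:
        return list(range(entry)), list(range(entry, len(x))), []
    return (
        list(range(entry)),
        list(range(entry, exit_i)),
        list(range(exit_i, len(x))),
    )


class TestSplit:
    def test_monotone_track(self, geometry):
        t = make_track(np.linspace(0, 300, 31))
        seg = split_at_constriction(t, geometry)
        assert seg.pre.size and seg.during.size and seg.post.size
        assert np.all(t.x[seg.pre] < 100.0)
        assert np.all(t.x[seg.post] > 120.0)

    def test_short_track_pre_only(self, geometry):
        t = make_track(np.linspace(0, 80, 9))
        seg = split_at_constriction(t, geometry)
        assert seg.pre.size == 9
        assert seg.during.size == 0 and seg.post.size == 0

    def test_oscillating_matches_brute_force(self, geometry):
        x = np.array([90.0, 102.0, 95.0, 108.0, 99.0, 115.0, 125.0, 130.0])
        t = make_track(x)
        seg = split_at_constriction(t, geometry)
        pre, during, post = brute_force_split(x, 100.0, 120.0)
        assert seg.pre.tolist() == pre
        assert seg.during.tolist() == during
        assert seg.post.tolist() == post

    def test_random_simulated_tracks_match_oracle(self, small_cohort, geometry):
        rng = np.random.default_rng(9)
        tracks = list(small_cohort.tracks)
        for t in rng.choice(len(tracks), size=10, replace=False):
            track = tracks[t]
            seg = split_at_constriction(track, geometry)
            pre, during, post = brute_force_split(track.x, 100.0, 120.0)
            assert seg.pre.tolist() == pre
            assert seg.during.tolist() == during
            assert seg.post.tolist() == post


class TestPeriSummary:
    def test_straight_tracks_ratio_one(self, geometry):
        tracks = [
            make_track(np.arange(0, 300, 6.0), track_id=i, dt=30.0)
            for i in range(5)
        ]
        ts = TrackSet(tracks=tuple(tracks), frame_interval=30.0, geometry=geometry)
        s = peri_summary(ts, n_boot=100, seed=0)
        assert s.crossing_fraction == 1.0
        assert s.ratios["speed_ratio"]["median"] == pytest.approx(1.0)
        assert s.ratios["dir_ratio"]["median"] == pytest.approx(1.0)

    def test_hand_built_track(self, geometry):
        # 6 points straddling the pillar; dt = 30 s
        x = np.array([80.0, 95.0, 110.0, 118.0, 130.0, 150.0])
        y = np.zeros(6)
        t = make_track(x, y, dt=30.0)
        ts = TrackSet(tracks=(t,), frame_interval=30.0, geometry=geometry)
        s = peri_summary(ts, n_boot=10, seed=0)
        row = s.per_cell.iloc[0]
        # pre: 80 -> 95 over 30 s = 30 um/min
        assert row["pre_speed"] == pytest.approx(30.0)
        assert row["pre_dir"] == pytest.approx(1.0)
        # post: 130 -> 150 over 30 s = 40 um/min
        assert row["post_speed"] == pytest.approx(40.0)
        assert row["post_euclidean"] == pytest.approx(20.0)
        assert row["crossing_frame"] == 4
        assert s.n_entered == 1 and s.n_crossed == 1

    def test_no_cell_crosses(self, geometry):
        tracks = [make_track([0.0, 30.0, 60.0], track_id=i) for i in range(3)]
        ts = TrackSet(tracks=tuple(tracks), frame_interval=60.0, geometry=geometry)
        s = peri_summary(ts, n_boot=10, seed=0)
        assert s.crossing_fraction == 0.0
        assert s.medians["post_speed"] is None

    def test_recovers_post_speed_factor(self):
        p = PhenotypeParams(label="rec", post_speed_factor=0.6)
        c = simulate_cohort(p, 200, seed=11)
        s = peri_summary(filter_tracks(c.tracks), n_boot=1000, seed=12)
        lo, hi = s.ratios["speed_ratio"]["ci95"]
        assert lo <= 0.6 <= hi

    def test_matches_brute_force_per_track(self, small_cohort, geometry):
        """Cohort summary equals per-frame brute-force on sampled tracks."""
        ts = small_cohort.tracks
        s = peri_summary(ts, n_boot=10, seed=0, exclude_saturated=False)
        rng = np.random.default_rng(3)
        tracks = list(ts)
        for i in rng.choice(len(tracks), size=10, replace=False):
            t = tracks[i]
            pre, during, post = brute_force_split(t.x, 100.0, 120.0)
            row = s.per_cell[s.per_cell.track_id == t.track_id].iloc[0]
            if len(pre) >= 2:
                seg_path = np.sum(np.hypot(np.diff(t.x[pre]), np.diff(t.y[pre])))
                elapsed = t.times[pre[-1]] - t.times[pre[0]]
                assert row["pre_speed"] == pytest.approx(seg_path / elapsed * 60.0)
            if len(post) >= 2:
                net = np.hypot(t.x[post[-1]] - t.x[post[0]],
                               t.y[post[-1]] - t.y[post[0]])
                path = np.sum(np.hypot(np.diff(t.x[post]), np.diff(t.y[post])))
                assert row["post_dir"] == pytest.approx(min(net / path, 1.0))

    def test_deterministic_given_seed(self, small_cohort):
        a = peri_summary(small_cohort.tracks, n_boot=200, seed=5)
        b = peri_summary(small_cohort.tracks, n_boot=200, seed=5)
        assert a.ratios == b.ratios
        pd.testing.assert_frame_equal(a.per_cell, b.per_cell)


class TestEccentricityTimecourse:
    def test_constant_attachment(self, geometry):
        x = np.linspace(0, 300, 31)
        t = make_track(x, eccentricity=np.full(31, 0.8))
        ts = TrackSet(tracks=(t,), frame_interval=60.0, geometry=geometry)
        out = eccentricity_timecourse(ts)
        for region in ("before", "during", "after"):
            assert out[region] == pytest.approx(0.8)

    def test_missing_attachment_errors(self, geometry):
        t = make_track([0.0, 10.0])
        ts = TrackSet(tracks=(t,), frame_interval=60.0, geometry=geometry)
        with pytest.raises(InvalidParameterError):
            eccentricity_timecourse(ts)

    def test_cells_without_during_excluded(self, geometry):
        t1 = make_track(np.linspace(0, 300, 31), track_id=0,
                        eccentricity=np.full(31, 0.9))
        t2 = make_track(np.linspace(0, 50, 31), track_id=1,
                        eccentricity=np.full(31, 0.3))
        ts = TrackSet(tracks=(t1, t2), frame_interval=60.0, geometry=geometry)
        out = eccentricity_timecourse(ts)
        assert out["during"] == pytest.approx(0.9)  # only t1 contributes

    def test_post_rise_detected(self):
        p = PhenotypeParams(label="pol", polarity_loss_prob=0.0,
                            ecc_pre=0.75, ecc_post_polarized=0.88)
        c = simulate_cohort(p, 50, seed=2)
        out = eccentricity_timecourse(c.tracks)
        assert out["after"] > out["before"]
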