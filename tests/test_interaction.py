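"""Nearby-interaction detection against a brute-force oracle, scores,
raster and peri-event speed profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalmetrics.interaction import (
    InteractionCriteria,
    detect_events,
    event_raster,
    interaction_scores,
    pair_distances,
    speed_profile,
)
from shoalmetrics.trajectory_io import ArenaSpec

from conftest import make_traj

BIG = ArenaSpec(width=1000.0, height=1000.0)


def oracle_events(dist_row, fps, max_distance, min_frames):
    """Exhaustive frame-scan event finder: literal re-reading of the
    criterion, independent of the vectorized implementation."""
    events = []
    run_start = None
    for t, d in enumerate(dist_row):
        close = (not np.isnan(d)) and d <= max_distance
        if close and run_start is None:
            run_start = t
        elif not close and run_start is not None:
            if t - run_start >= min_frames:
                events.append((run_start, t))
            run_start = None
    if run_start is not None and len(dist_row) - run_start >= min_frames:
        events.append((run_start, len(dist_row)))
    return events


def two_fish(d_series, fps=20.0):
    """Two fish on the x-axis with prescribed pairwise distances."""
    T = len(d_series)
    xy = np.zeros((T, 2, 2))
    xy[:, 0, :] = [500.0, 500.0]
    xy[:, 1, 0] = 500.0 + np.asarray(d_series)
    xy[:, 1, 1] = 500.0
    return make_traj(xy, fps=fps, arena=BIG)


class TestPairDistances:
    def test_four_fish_give_six_pairs(self):
        xy = np.tile([[1.0, 1], [2, 2], [3, 3], [4, 4]], (10, 1, 1))
        pairs, dist = pair_distances(make_traj(xy, arena=BIG))
        assert len(pairs) == 6
        assert dist.shape == (6, 10)

    def test_three_four_five_triangle(self):
        xy = np.tile([[[0.0, 0.0], [3.0, 4.0]]], (5, 1, 1))
        _, dist = pair_distances(make_traj(xy, arena=BIG))
        np.testing.assert_allclose(dist, 5.0)

    def test_missing_fish_gives_missing_distance(self):
        xy = np.tile([[[0.0, 0.0], [3.0, 4.0]]], (5, 1, 1))
        xy[2, 1, :] = np.nan
        _, dist = pair_distances(make_traj(xy, arena=BIG))
        assert np.isnan(dist[0, 2])
        assert np.isfinite(dist[0, [0, 1, 3, 4]]).all()

    def test_single_fish_errors(self):
        xy = np.zeros((5, 1, 2)) + 1.0
        with pytest.raises(ValueError):
            pair_distances(make_traj(xy, arena=BIG))


class TestDetectEvents:
    def test_100_close_frames_is_five_second_event(self):
        d = np.full(300, 10.0)
        d[50:150] = 3.0
        events = detect_events(two_fish(d))
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(5.0)
        assert (events[0].start_frame, events[0].end_frame) == (50, 150)

    def test_never_close_no_events(self):
        assert detect_events(two_fish(np.full(300, 10.0))) == []

    def test_colocated_whole_assay_single_event(self):
        events = detect_events(two_fish(np.zeros(6000)))
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(300.0)

    def test_duration_boundary_inclusive_at_four_seconds(self):
        d79 = np.full(300, 10.0)
        d79[100:179] = 1.0  # 79 frames = 3.95 s
        d80 = np.full(300, 10.0)
        d80[100:180] = 1.0  # 80 frames = 4.00 s
        assert detect_events(two_fish(d79)) == []
        assert len(detect_events(two_fish(d80))) == 1

    def test_strict_boundary_excludes_exact_minimum(self):
        d80 = np.full(300, 10.0)
        d80[100:180] = 1.0
        crit = InteractionCriteria(inclusive=False)
        assert detect_events(two_fish(d80), crit) == []
        d81 = np.full(300, 10.0)
        d81[100:181] = 1.0
        assert len(detect_events(two_fish(d81), crit)) == 1

    def test_missing_frames_break_runs(self):
        d = np.full(400, 1.0)
        d[200] = np.nan
        events = detect_events(two_fish(d))
        assert [(e.start_frame, e.end_frame) for e in events] == [
            (0, 200),
            (201, 400),
        ]

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_oracle_on_random_series(self, data):
        T = data.draw(st.integers(20, 500))
        # random walk of distances crossing the threshold repeatedly
        steps = data.draw(
            st.lists(
                st.floats(-2.0, 2.0, allow_nan=False), min_size=T, max_size=T
            )
        )
        d = np.abs(4.0 + np.cumsum(steps))
        traj = two_fish(d)
        crit = InteractionCriteria()
        got = [(e.start_frame, e.end_frame) for e in detect_events(traj, crit)]
        want = oracle_events(d, 20.0, 5.0, crit.min_frames(20.0))
        assert got == want

    def test_monotone_in_criteria(self):
        rng = np.random.default_rng(3)
        d = np.abs(5.0 + np.cumsum(rng.normal(0, 1.5, 600)))
        traj = two_fish(d)
        base = interaction_scores(detect_events(traj), traj)
        wider = interaction_scores(
            detect_events(traj, InteractionCriteria(max_distance=8.0)), traj
        )
        shorter = interaction_scores(
            detect_events(traj, InteractionCriteria(min_duration=2.0)), traj
        )
        assert wider.duration_s >= base.duration_s
        assert shorter.duration_s >= base.duration_s
        assert shorter.count >= base.count


class TestScoresAndRaster:
    def test_scores_are_additive(self):
        d = np.full(600, 10.0)
        d[0:100] = 1.0  # 5.0 s
        d[300:450] = 1.0  # 7.5 s
        traj = two_fish(d)
        scores = interaction_scores(detect_events(traj), traj)
        assert scores.duration_s == pytest.approx(12.5)
        assert scores.count == 2

    def test_empty_event_list_scores_zero(self):
        traj = two_fish(np.full(100, 10.0))
        scores = interaction_scores([], traj)
        assert (scores.duration_s, scores.count) == (0.0, 0)

    def test_raster_row_sums_match_durations(self):
        rng = np.random.default_rng(5)
        xy = np.stack(
            [rng.uniform(0, 49.5, (2000, 4)), rng.uniform(0, 24.2, (2000, 4))],
            axis=2,
        )
        # slow the walk down so proximity persists
        xy = np.cumsum(xy - xy.mean(axis=0), axis=0) * 0.001 + 12.0
        traj = make_traj(xy, arena=BIG)
        events = detect_events(traj)
        pairs, raster = event_raster(events, traj)
        scores = interaction_scores(events, traj)
        for p, row in zip(pairs, raster):
            dur, _ = scores.per_pair[p]
            assert row.sum() / traj.fps == pytest.approx(dur)

    def test_raster_empty_is_zero(self):
        traj = two_fish(np.full(100, 10.0))
        _, raster = event_raster([], traj)
        assert raster.sum() == 0


class TestSpeedProfile:
    def test_constant_speed_all_means_equal(self):
        # two fish side by side moving at 2 cm/s, one long event
        T = 400
        x = 100.0 + np.arange(T) * 0.1  # 2 cm/s at 20 fps
        xy = np.zeros((T, 2, 2))
        xy[:, 0, 0] = x
        xy[:, 0, 1] = 500.0
        xy[:, 1, 0] = x
        xy[:, 1, 1] = 503.0
        traj = make_traj(xy, arena=BIG)
        events = detect_events(traj)
        assert len(events) == 1
        prof = speed_profile(traj, events)
        assert prof[0].during_mean == pytest.approx(2.0)

    def test_stationary_fish_zero_means(self):
        xy = np.tile([[[1.0, 1.0], [2.0, 1.0]]], (200, 1, 1))
        traj = make_traj(xy, arena=BIG)
        events = detect_events(traj)
        prof = speed_profile(traj, events)
        assert prof[0].during_mean == pytest.approx(0.0)

    def test_fish_without_events_reports_missing(self):
        traj = two_fish(np.full(300, 10.0))
        prof = speed_profile(traj, [])
        assert np.isnan(prof[0].during_mean)
        assert np.isnan(prof[0].before_mean)

    def test_categories_partition_known_epochs(self):
        # event frames [100, 200); before/after windows of 4 s = 80 frames
        d = np.full(400, 10.0)
        d[100:200] = 1.0
        traj = two_fish(d)
        events = detect_events(traj)
        # piecewise speed: 1 cm/s outside, 3 cm/s inside the event window
        T = 400
        x = np.empty(T)
        x[0] = 100.0
        speed = np.where((np.arange(T - 1) >= 100) & (np.arange(T - 1) < 200), 3.0, 1.0)
        x[1:] = x[0] + np.cumsum(speed / 20.0)
        xy = np.zeros((T, 2, 2))
        xy[:, 0, 0] = x
        xy[:, 0, 1] = 500.0
        xy[:, 1, 0] = x + d * 0  # fish 2 mirrors fish 1 shifted by d
        xy[:, 1, 0] = x + d
        xy[:, 1, 1] = 500.0
        traj = make_traj(xy, arena=BIG)
        prof = speed_profile(traj, events)
        assert prof[0].during_mean == pytest.approx(3.0, rel=0.02)
        assert prof[0].before_mean == pytest.approx(1.0, rel=0.02)
        assert prof[0].after_mean == pytest.approx(1.0, rel=0.02)
        assert prof[0].out_of_event_mean == pytest.approx(1.0, rel=0.02)
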