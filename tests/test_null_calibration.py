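"""Permutation-null construction, empirical p-values and duration
calibration."""

import numpy as np
import pytest

from shoalmetrics.interaction import InteractionCriteria, detect_events, interaction_scores
from shoalmetrics.null_calibration import (
    NullDistribution,
    calibrate_min_duration,
    exceeds_chance,
    permute,
    score_positions,
)
from shoalmetrics.synthetic_data import SimConfig, simulate_group
from shoalmetrics.trajectory_io import ArenaSpec

from conftest import make_traj


def independent_groups(n, duration_s=60.0, seed0=9000):
    out = []
    for s in range(n):
        traj, _ = simulate_group(
            SimConfig(
                seed=seed0 + s,
                duration_s=duration_s,
                social_on_rate=0.0,
                social_off_rate=0.0,
            )
        )
        out.append(traj)
    return out


class TestScorePositions:
    def test_matches_detector_pipeline(self):
        traj, _ = simulate_group(SimConfig(seed=3, duration_s=60.0))
        crit = InteractionCriteria()
        via_events = interaction_scores(detect_events(traj, crit), traj)
        assert score_positions(traj.xy, traj.fps, crit) == pytest.approx(
            via_events.duration_s
        )
        assert score_positions(
            traj.xy, traj.fps, crit, score="count"
        ) == pytest.approx(via_events.count)


class TestPermute:
    def test_seed_reproducibility(self):
        groups = independent_groups(5, duration_s=30.0)
        a = permute(groups, "cross_group", n=20, seed=42)
        b = permute(groups, "cross_group", n=20, seed=42)
        np.testing.assert_array_equal(a.replicate_scores, b.replicate_scores)

    def test_cross_group_needs_enough_groups(self):
        groups = independent_groups(2, duration_s=30.0)
        with pytest.raises(ValueError, match="cross_group"):
            permute(groups, "cross_group", n=5, seed=0)

    def test_time_shift_of_constant_pair_is_invariant(self):
        xy = np.tile([[[1.0, 1.0], [2.0, 1.0]]], (6000, 1, 1))
        traj = make_traj(xy, arena=ArenaSpec())
        null = permute([traj], "time_shift", n=10, seed=1)
        np.testing.assert_allclose(null.replicate_scores, 300.0)

    def test_time_shift_preserves_speed_histogram(self):
        # a circular shift keeps every per-frame step except that it trades
        # the step at the cut for the wrap-around step; the remaining
        # multiset of speeds is identical
        traj, _ = simulate_group(SimConfig(seed=5, duration_s=30.0))
        T = traj.duration_frames
        rng = np.random.default_rng(0)
        for f in range(traj.n_fish):
            off = int(rng.integers(100, 500))
            series = traj.xy[:, f, :]
            shifted = np.roll(series, off, axis=0)

            def steps(a):
                d = np.diff(a, axis=0)
                return np.hypot(d[:, 0], d[:, 1])

            orig = np.delete(steps(series), T - off - 1)
            perm = np.delete(steps(shifted), off - 1)
            np.testing.assert_allclose(np.sort(orig), np.sort(perm))

    def test_null_mean_close_to_observed_mean_under_independence(self):
        groups = independent_groups(12, duration_s=120.0)
        crit = InteractionCriteria()
        observed = [score_positions(g.xy, g.fps, crit) for g in groups]
        null = permute(groups, "cross_group", n=300, seed=7, crit=crit)
        # under independence real groups ARE chance groups
        assert np.mean(null.replicate_scores) == pytest.approx(
            np.mean(observed), abs=3.0 * np.std(observed)
        )


class TestExceedsChance:
    def test_add_one_formula(self):
        null = NullDistribution(
            replicate_scores=np.arange(1000.0), n_permutations=1000, method="cross_group"
        )
        assert exceeds_chance(2000.0, null) == pytest.approx(1 / 1001)

    def test_median_observed_p_about_half(self):
        null = NullDistribution(
            replicate_scores=np.arange(1001.0), n_permutations=1001, method="cross_group"
        )
        assert exceeds_chance(500.0, null) == pytest.approx(0.5, abs=0.01)

    def test_social_groups_rejected_against_cross_group_null(self):
        donors = independent_groups(8, duration_s=120.0)
        null = permute(donors, "cross_group", n=99, seed=11)
        hits = 0
        n_social = 15
        for s in range(n_social):
            traj, _ = simulate_group(
                SimConfig(
                    seed=7000 + s,
                    duration_s=120.0,
                    attraction=0.9,
                    social_on_rate=0.2,
                )
            )
            obs = score_positions(traj.xy, traj.fps, InteractionCriteria())
            if exceeds_chance(obs, null) < 0.05:
                hits += 1
        assert hits >= int(0.9 * n_social)


class TestCalibrateMinDuration:
    def test_degenerate_grid_returns_four_seconds_or_flagged(self):
        groups = independent_groups(5, duration_s=60.0)
        res = calibrate_min_duration(groups, grid=[4.0], n=50, seed=0)
        assert res.min_duration_s == 4.0

    def test_expected_counts_decrease_with_duration(self):
        groups = independent_groups(6, duration_s=120.0)
        res = calibrate_min_duration(
            groups, grid=[0.5, 1.0, 2.0, 4.0, 8.0], n=100, seed=2
        )
        counts = [res.expected_chance_counts[tau] for tau in sorted(res.expected_chance_counts)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_chosen_tau_nondecreasing_in_walker_density(self):
        # denser groups (more fish in the same arena) produce more chance
        # proximity, so the calibrated duration criterion cannot shrink
        taus = []
        for n_fish in (2, 6):
            groups = []
            for s in range(6):
                traj, _ = simulate_group(
                    SimConfig(
                        seed=500 + s,
                        n_fish=n_fish,
                        duration_s=120.0,
                        social_on_rate=0.0,
                        social_off_rate=0.0,
                    )
                )
                groups.append(traj)
            res = calibrate_min_duration(
                groups, grid=[0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0],
                alpha=0.5, n=60, seed=3,
            )
            taus.append(res.min_duration_s)
        assert taus[0] <= taus[1]
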