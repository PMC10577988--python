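"""Permutation nulls for the nearby-interaction criterion.

Observed affinity scores are compared against a chance-encounter null built
by permuting trajectories:

* ``cross_group`` — each null replicate assembles a *virtual group* whose
  members are real trajectories drawn from distinct recorded groups, so any
  proximity between them is coincidental. This is the standard chance null
  for shoaling assays and the default whenever enough groups exist.
* ``time_shift`` — each fish's series is circularly shifted by an
  independent random offset, destroying cross-fish synchrony while keeping
  each path's marginal statistics exactly.

Both schemes score every replicate with the same detector and criteria as
the observed data; the empirical p-value uses the add-one estimator
``p = (1 + #{null >= observed}) / (n + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interaction import InteractionCriteria, fish_pairs, _runs
from .trajectory_io import TrajectorySet

__all__ = [
    "NullDistribution",
    "CalibrationResult",
    "score_positions",
    "permute",
    "exceeds_chance",
    "calibrate_min_duration",
]


@dataclass(frozen=True)
class NullDistribution:
    """Group scores under a permutation scheme."""

    replicate_scores: np.ndarray
    n_permutations: int
    method: str
    alpha: float = 0.05
    score: str = "duration"
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)

    def __post_init__(self) -> None:
        scores = np.asarray(self.replicate_scores, dtype=float)
        object.__setattr__(self, "replicate_scores", scores)
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if np.any(scores < 0):
            raise ValueError("scores must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of duration-criterion calibration against a null."""

    min_duration_s: float
    flagged: bool
    expected_chance_counts: dict[float, float]
    null_event_durations_s: np.ndarray


def _pair_run_lengths(xy: np.ndarray, max_distance: float) -> list[np.ndarray]:
    """Lengths (frames) of maximal proximity runs for each unordered pair."""
    n_fish = xy.shape[1]
    out = []
    for i, j in fish_pairs(n_fish):
        d = xy[:, i, :] - xy[:, j, :]
        dist = np.hypot(d[:, 0], d[:, 1])
        with np.errstate(invalid="ignore"):
            close = dist <= max_distance
        runs = _runs(close)
        out.append(runs[:, 1] - runs[:, 0])
    return out


def score_positions(
    xy: np.ndarray,
    fps: float,
    crit: InteractionCriteria,
    score: str = "duration",
) -> float:
    """Group affinity score straight from a position array.

    Equivalent to ``detect_events`` + ``interaction_scores`` but without
    constructing intermediate objects, so permutation loops stay cheap.
    ``score`` is ``"duration"`` (total qualifying-event seconds) or
    ``"count"`` (number of qualifying events).
    """
    min_f = crit.min_frames(fps)
    total_frames = 0
    total_events = 0
    for lengths in _pair_run_lengths(xy, crit.max_distance):
        ok = lengths[lengths >= min_f]
        total_frames += int(ok.sum())
        total_events += int(ok.size)
    if score == "duration":
        return total_frames / fps
    if score == "count":
        return float(total_events)
    raise ValueError(f"unknown score {score!r}")


def _check_compatible(trajs: list[TrajectorySet]) -> None:
    t0 = trajs[0]
    for t in trajs[1:]:
        if t.fps != t0.fps or t.n_fish != t0.n_fish:
            raise ValueError("all groups must share fps and group size")
        if (t.arena.width, t.arena.height) != (t0.arena.width, t0.arena.height):
            raise ValueError("all groups must share the arena geometry")
        if t.duration_frames != t0.duration_frames:
            raise ValueError("all groups must share the recording length")


def permute(
    trajs: list[TrajectorySet],
    method: str = "cross_group",
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    crit: InteractionCriteria | None = None,
    alpha: float = 0.05,
    score: str = "duration",
) -> NullDistribution:
    """Build a permutation null of group affinity scores.

    ``cross_group`` draws, for each replicate, one member trajectory from
    each of ``n_fish`` distinct real groups (so at least ``n_fish`` groups
    are required); ``time_shift`` works on a single group. Reproducible
    given ``seed``.
    """
    crit = crit or InteractionCriteria()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if not trajs:
        raise ValueError("no trajectories given")
    _check_compatible(trajs)
    fps = trajs[0].fps
    n_fish = trajs[0].n_fish
    T = trajs[0].duration_frames
    scores = np.empty(n)

    if method == "cross_group":
        if len(trajs) < 2:
            raise ValueError("cross_group permutation needs at least two groups")
        if len(trajs) < n_fish:
            raise ValueError(
                f"cross_group needs >= {n_fish} groups so each virtual-group "
                "member comes from a distinct real group; use time_shift instead"
            )
        stack = np.stack([t.xy for t in trajs])  # (G, T, F, 2)
        G = len(trajs)
        for r in range(n):
            gsel = rng.choice(G, size=n_fish, replace=False)
            fsel = rng.integers(0, n_fish, size=n_fish)
            virtual = np.transpose(stack[gsel, :, fsel, :], (1, 0, 2))
            scores[r] = score_positions(virtual, fps, crit, score)
    elif method == "time_shift":
        traj = trajs[0]
        min_off = min(crit.min_frames(fps), max(T - 1, 1))
        hi = T - min_off
        if hi <= min_off:
            min_off, hi = 1, T
        for r in range(n):
            offs = rng.integers(min_off, hi, size=n_fish)
            shifted = np.empty_like(traj.xy)
            for f in range(n_fish):
                shifted[:, f, :] = np.roll(traj.xy[:, f, :], int(offs[f]), axis=0)
            scores[r] = score_positions(shifted, fps, crit, score)
    else:
        raise ValueError(f"unknown permutation method {method!r}")

    return NullDistribution(
        replicate_scores=scores,
        n_permutations=n,
        method=method,
        alpha=alpha,
        score=score,
        criteria=crit,
    )


def exceeds_chance(observed: float, null: NullDistribution) -> float:
    """Add-one empirical p-value of the observed score under the null."""
    scores = null.replicate_scores
    if scores.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(scores >= observed)) / (scores.size + 1))


def calibrate_min_duration(
    trajs: list[TrajectorySet],
    max_distance: float = 5.0,
    alpha: float = 0.05,
    grid: list[float] | None = None,
    method: str = "cross_group",
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CalibrationResult:
    """Choose the duration criterion from the null event-duration spectrum.

    For each candidate duration tau, the expected per-group number of
    *chance* proximity events lasting >= tau is estimated from ``n``
    permutation replicates (distance fixed at ``max_distance``). The chosen
    criterion is the smallest grid value whose expected chance count is
    <= ``alpha``; if no grid value qualifies, the largest is returned
    flagged.
    """
    grid = sorted(grid or [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0])
    if not grid:
        raise ValueError("empty duration grid")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    _check_compatible(trajs)
    fps = trajs[0].fps
    n_fish = trajs[0].n_fish
    T = trajs[0].duration_frames

    durations: list[np.ndarray] = []
    if method == "cross_group":
        if len(trajs) < n_fish:
            raise ValueError(
                f"cross_group calibration needs >= {n_fish} groups"
            )
        stack = np.stack([t.xy for t in trajs])
        G = len(trajs)
        for _ in range(n):
            gsel = rng.choice(G, size=n_fish, replace=False)
            fsel = rng.integers(0, n_fish, size=n_fish)
            virtual = np.transpose(stack[gsel, :, fsel, :], (1, 0, 2))
            for lengths in _pair_run_lengths(virtual, max_distance):
                durations.append(lengths / fps)
    elif method == "time_shift":
        traj = trajs[0]
        for _ in range(n):
            offs = rng.integers(1, T, size=n_fish)
            shifted = np.empty_like(traj.xy)
            for f in range(n_fish):
                shifted[:, f, :] = np.roll(traj.xy[:, f, :], int(offs[f]), axis=0)
            for lengths in _pair_run_lengths(shifted, max_distance):
                durations.append(lengths / fps)
    else:
        raise ValueError(f"unknown permutation method {method!r}")

    all_durations = (
        np.concatenate(durations) if durations else np.empty(0, dtype=float)
    )
    expected = {
        tau: float(np.sum(all_durations >= tau) / n) for tau in grid
    }
    for tau in grid:
        if expected[tau] <= alpha:
            return CalibrationResult(tau, False, expected, all_durations)
    return CalibrationResult(grid[-1], True, expected, all_durations)
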