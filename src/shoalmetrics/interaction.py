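"""Pairwise nearby-interaction detection and social-affinity scores.

A *nearby interaction* is the operational unit of social affinity in group
assays of Astyanax mexicanus: two fish staying within ``max_distance``
(default 5 cm) of each other for at least ``min_duration`` (default 4 s).
Group-level affinity is summarized as the total duration and the number of
such events across all unordered pairs in the assay window, and the
peri-event speed profile (before / during / after / out-of-event) captures
the characteristic slow-down during interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory_io import TrajectorySet

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "GroupScores",
    "SpeedProfile",
    "pair_distances",
    "detect_events",
    "interaction_scores",
    "event_raster",
    "speed_profile",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """Proximity/duration criterion for a nearby-interaction event.

    ``min_duration`` is inclusive: a run lasting exactly ``min_duration``
    seconds qualifies. Set ``inclusive=False`` for a strict ``>`` reading.
    """

    max_distance: float = 5.0
    min_duration: float = 4.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.max_distance > 0 and self.min_duration > 0):
            raise ValueError("max_distance and min_duration must be positive")

    def min_frames(self, fps: float) -> int:
        """Smallest qualifying run length in frames at the given frame rate."""
        n = self.min_duration * fps
        if self.inclusive:
            return int(np.ceil(n - 1e-9))
        return int(np.floor(n + 1e-9)) + 1


@dataclass(frozen=True)
class InteractionEvent:
    """One sustained-proximity bout of one unordered pair.

    Frames are half-open ``[start_frame, end_frame)``.
    """

    pair: tuple[int, int]
    start_frame: int
    end_frame: int
    duration_s: float


@dataclass(frozen=True)
class GroupScores:
    """Group-level affinity: total event duration (s) and event count,
    summed over all pairs, with the per-pair breakdown retained."""

    duration_s: float
    count: int
    per_pair: dict[tuple[int, int], tuple[float, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class SpeedProfile:
    """Mean speed (cm/s) of one fish around its interaction events."""

    fish: int
    before_mean: float
    during_mean: float
    after_mean: float
    out_of_event_mean: float
    window_s: float = 4.0


def fish_pairs(n_fish: int) -> list[tuple[int, int]]:
    """All unordered pairs (i < j); four fish give six pairs."""
    return list(itertools.combinations(range(n_fish), 2))


def pair_distances(traj: TrajectorySet) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Per-frame Euclidean distance for every unordered pair.

    Returns the pair list and a ``(n_pairs, frames)`` array; the distance is
    NaN whenever either fish is missing in that frame.
    """
    if traj.n_fish < 2:
        raise ValueError("pair distances need at least two fish")
    pairs = fish_pairs(traj.n_fish)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    d = traj.xy[:, ii, :] - traj.xy[:, jj, :]  # (T, P, 2)
    return pairs, np.hypot(d[..., 0], d[..., 1]).T.copy()


def _runs(mask: np.ndarray) -> np.ndarray:
    """Maximal True runs of a 1-D boolean mask as an ``(n, 2)`` array of
    half-open ``[start, end)`` pairs."""
    edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return edges.reshape(-1, 2)


def detect_events(
    traj: TrajectorySet, crit: InteractionCriteria | None = None
) -> list[InteractionEvent]:
    """Detect nearby-interaction events for every pair.

    A qualifying event is a maximal run of consecutive frames with pair
    distance <= ``crit.max_distance`` whose length meets the duration
    criterion. Frames with a missing distance break runs. Events are sorted
    by start frame (ties by pair).
    """
    crit = crit or InteractionCriteria()
    pairs, dist = pair_distances(traj)
    min_f = crit.min_frames(traj.fps)
    events: list[InteractionEvent] = []
    for pair, row in zip(pairs, dist):
        with np.errstate(invalid="ignore"):
            close = row <= crit.max_distance
        for s, e in _runs(close):
            if e - s >= min_f:
                events.append(
                    InteractionEvent(
                        pair=pair,
                        start_frame=int(s),
                        end_frame=int(e),
                        duration_s=(int(e) - int(s)) / traj.fps,
                    )
                )
    events.sort(key=lambda ev: (ev.start_frame, ev.pair))
    return events


def interaction_scores(
    events: list[InteractionEvent], traj: TrajectorySet
) -> GroupScores:
    """Sum event durations and counts over all pairs of one assay window."""
    per_pair: dict[tuple[int, int], tuple[float, int]] = {
        p: (0.0, 0) for p in fish_pairs(traj.n_fish)
    }
    for ev in events:
        d, c = per_pair[ev.pair]
        per_pair[ev.pair] = (d + ev.duration_s, c + 1)
    return GroupScores(
        duration_s=float(sum(d for d, _ in per_pair.values())),
        count=int(sum(c for _, c in per_pair.values())),
        per_pair=per_pair,
    )


def event_raster(
    events: list[InteractionEvent], traj: TrajectorySet
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Binary pair x frame occupancy matrix (1 inside an event)."""
    pairs = fish_pairs(traj.n_fish)
    index = {p: i for i, p in enumerate(pairs)}
    raster = np.zeros((len(pairs), traj.duration_frames), dtype=np.uint8)
    for ev in events:
        raster[index[ev.pair], ev.start_frame : ev.end_frame] = 1
    return pairs, raster


def events_to_frame(events: list[InteractionEvent], fps: float) -> pd.DataFrame:
    """Events as a tidy table (pair, start_s, end_s, duration_s)."""
    return pd.DataFrame(
        {
            "pair": [f"{a}-{b}" for a, b in (ev.pair for ev in events)],
            "start_s": [ev.start_frame / fps for ev in events],
            "end_s": [ev.end_frame / fps for ev in events],
            "duration_s": [ev.duration_s for ev in events],
        }
    )


# peri-event category codes
_OUT, _BEFORE, _DURING, _AFTER = 0, 1, 2, 3


def speed_profile(
    traj: TrajectorySet,
    events: list[InteractionEvent],
    window_s: float = 4.0,
) -> list[SpeedProfile]:
    """Mean speed before / during / after events and out of events, per fish.

    The per-frame speed series (1-frame displacements, no smoothing) is
    partitioned exclusively: frames inside any of the fish's events are
    *during*; frames within ``window_s`` before a start (after an end) are
    *before* (*after*), a contested frame going to the nearer event; all
    remaining frames are *out-of-event*. Fish with no events get NaN for
    the three peri-event means.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    speeds = traj.speeds()  # (T-1, F); speed[t] spans frames t -> t+1
    n_speed = speeds.shape[0]
    w = int(round(window_s * traj.fps))
    profiles: list[SpeedProfile] = []
    for f in range(traj.n_fish):
        evs = [ev for ev in events if f in ev.pair]
        cat = np.zeros(n_speed, dtype=np.int8)
        owner_dist = np.full(n_speed, np.iinfo(np.int64).max, dtype=np.int64)
        for ev in evs:
            s, e = ev.start_frame, min(ev.end_frame, n_speed)
            cat[s:e] = _DURING
            owner_dist[s:e] = 0
        for ev in evs:
            s, e = ev.start_frame, ev.end_frame
            for lo, hi, code in (
                (max(s - w, 0), min(s, n_speed), _BEFORE),
                (min(e, n_speed), min(e + w, n_speed), _AFTER),
            ):
                for t in range(lo, hi):
                    if cat[t] == _DURING:
                        continue
                    d = (s - t) if code == _BEFORE else (t - e + 1)
                    if d < owner_dist[t]:
                        owner_dist[t] = d
                        cat[t] = code
        col = speeds[:, f]

        def _mean(code: int) -> float:
            sel = col[(cat == code) & ~np.isnan(col)]
            return float(sel.mean()) if sel.size else float("nan")

        if evs:
            profiles.append(
                SpeedProfile(
                    fish=f,
                    before_mean=_mean(_BEFORE),
                    during_mean=_mean(_DURING),
                    after_mean=_mean(_AFTER),
                    out_of_event_mean=_mean(_OUT),
                    window_s=window_s,
                )
            )
        else:
            nan = float("nan")
            profiles.append(
                SpeedProfile(
                    fish=f,
                    before_mean=nan,
                    during_mean=nan,
                    after_mean=nan,
                    out_of_event_mean=_mean(_OUT),
                    window_s=window_s,
                )
            )
    return profiles
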