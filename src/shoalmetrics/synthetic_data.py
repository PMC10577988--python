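"""Synthetic group-trajectory generator with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in a four-fish group assay (20 frames/s, 49.5 x 24.2 cm arena):

* each fish is a correlated random walk — per-frame heading increments are
  a deterministic lateral turn term plus von Mises noise, speed is drawn
  around ``mean_speed``;
* *social affinity* is a pair-level two-state Markov process with at most
  one pair in the social state at a time (social bouts are dyadic and
  exclusive, as in the event rasters the pipeline produces). Bouts are
  encounter-triggered: while no bout runs, one starts at
  ``social_on_rate`` per second for a pair chosen uniformly among pairs
  currently within ``social_onset_radius_cm``, and ends at
  ``social_off_rate``. While a pair is social, a follower (chosen
  uniformly at bout onset) steers toward its partner, closing a fraction
  ``attraction`` of its heading error per second, and both members swim
  slower by a factor ``1 - attraction * (1 - social_speed_factor)`` (the
  social gain scales steering and slow-down together: at full attraction
  the speed drops to ``social_speed_factor`` times baseline, at zero
  attraction the state is behaviorally inert), reproducing the slow-down
  observed during nearby interactions;
* *turning bias* enters as a per-window (default five-frame) turn whose
  sign is left with probability ``left_bias``;
* the 24-h single-fish sleep mode alternates exponential active/quiescent
  dwells; quiescent fish jitter around a rest point well below any
  reasonable immobility threshold.

Walls reflect specularly; on contact the heading noise is re-drawn so fish
do not get trapped in corners. All randomness flows from one seeded
generator, so every simulation is reproducible bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .trajectory_io import ArenaSpec, TrajectorySet, write_trajectories

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_group",
    "simulate_sleep_track",
    "write_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the trajectory generator.

    Rates are per second; ``attraction`` in [0, 1] scales how strongly a
    follower steers toward its partner in the social state, and
    ``social_speed_factor`` (< 1 slows) multiplies speed inside it.
    ``social_on_rate`` is the group-level rate at which a social bout
    starts while no bout is running (for a pair chosen uniformly among
    those within ``social_onset_radius_cm`` at that moment — bouts are
    encounter-triggered); ``social_off_rate`` ends the running bout, so
    bouts last ``1 / social_off_rate`` seconds on average.
    """

    n_fish: int = 4
    fps: float = 20.0
    duration_s: float = 300.0
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    mean_speed: float = 4.0
    sd_speed: float = 1.0
    heading_concentration: float = 50.0  # von Mises kappa, per frame
    attraction: float = 0.0
    social_on_rate: float = 0.05
    social_off_rate: float = 0.05
    social_onset_radius_cm: float = 5.0
    social_speed_factor: float = 0.7
    left_bias: float = 0.5
    turn_magnitude: float = 0.35  # rad per turn window
    turn_window_frames: int = 5
    sleep_on_rate: float = 0.0
    sleep_off_rate: float = 0.0
    quiescent_jitter_cm: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.attraction <= 1):
            raise ValueError("attraction must be in [0, 1]")
        if not (0 < self.social_speed_factor <= 1):
            raise ValueError("social_speed_factor must be in (0, 1]")
        if not (0 <= self.left_bias <= 1):
            raise ValueError("left_bias must be a probability")
        if min(self.social_on_rate, self.social_off_rate) < 0:
            raise ValueError("switching rates must be >= 0")
        if min(self.sleep_on_rate, self.sleep_off_rate) < 0:
            raise ValueError("sleep rates must be >= 0")
        if self.mean_speed < 0 or self.sd_speed < 0:
            raise ValueError("speeds must be >= 0")
        if self.n_fish < 1 or self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("invalid group size, fps or duration")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    social_intervals: dict[tuple[int, int], list[tuple[int, int]]]
    followers: dict[tuple[int, int], list[int]]
    turn_signs: np.ndarray  # (n_blocks, n_fish), +1 left / -1 right
    sleep_intervals: list[tuple[int, int]] = field(default_factory=list)


#: maximal per-frame heading-blend weight (at attraction 1) at the
#: reference frame rate; sets how sharply a follower can steer
_W_MAX = 0.2
_FPS_REF = 20.0


def _fold(u: np.ndarray, width: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, width] by specular reflection."""
    period = 2 * width
    v = np.mod(u, period)
    return np.where(v > width, period - v, v)


def simulate_group(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate one group assay; returns the trajectories and ground truth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    T = int(round(cfg.duration_s * cfg.fps))
    F = cfg.n_fish
    W, H = cfg.arena.width, cfg.arena.height
    pairs = list(itertools.combinations(range(F), 2))
    P = len(pairs)

    # pre-drawn randomness (vectorized; the frame loop only consumes it)
    noise = rng.vonmises(0.0, cfg.heading_concentration, size=(T, F))
    base_speed = np.clip(rng.normal(cfg.mean_speed, cfg.sd_speed, size=(T, F)), 0.05, None)
    w = cfg.turn_window_frames
    n_blocks = max(T // w, 1)
    turn_signs = np.where(rng.random((n_blocks, F)) < cfg.left_bias, 1.0, -1.0)
    per_frame_turn = np.repeat(turn_signs * cfg.turn_magnitude / w, w, axis=0)[:T]
    if per_frame_turn.shape[0] < T:  # trailing partial block keeps last sign
        pad = np.repeat(per_frame_turn[-1:], T - per_frame_turn.shape[0], axis=0)
        per_frame_turn = np.vstack([per_frame_turn, pad])
    u_switch = rng.random(T)
    p_on = min(cfg.social_on_rate / cfg.fps, 1.0)
    # affinity prolongs engagements: the expected bout length grows from
    # 1/off_rate at zero gain to 3/off_rate at full gain
    p_off = min(
        cfg.social_off_rate / (1.0 + 2.0 * cfg.attraction) / cfg.fps, 1.0
    )

    pos = np.column_stack([rng.uniform(0, W, F), rng.uniform(0, H, F)])
    heading = rng.uniform(-np.pi, np.pi, F)
    xy = np.empty((T, F, 2))

    active_k = -1  # index into pairs of the one social pair, -1 = none
    follower_id = -1
    onset = 0
    intervals: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    followers: dict[tuple[int, int], list[int]] = {p: [] for p in pairs}

    dt = 1.0 / cfg.fps
    for t in range(T):
        # exclusive social-bout switching: at most one pair is social, and
        # a bout can only start between fish that have just encountered
        # each other (pair within the onset radius)
        if active_k >= 0:
            if u_switch[t] < p_off:
                intervals[pairs[active_k]].append((onset, t))
                active_k = -1
        elif u_switch[t] < p_on and P > 0:
            near = [
                k
                for k, (i, j) in enumerate(pairs)
                if np.hypot(*(pos[i] - pos[j])) <= cfg.social_onset_radius_cm
            ]
            if near:
                active_k = near[int(rng.integers(0, len(near)))]
                onset = t
                follower_id = pairs[active_k][int(rng.integers(0, 2))]
                followers[pairs[active_k]].append(follower_id)

        heading = heading + per_frame_turn[t] + noise[t]
        social_member = np.zeros(F, dtype=bool)
        if active_k >= 0:
            i, j = pairs[active_k]
            social_member[i] = social_member[j] = True
            if cfg.attraction > 0:
                fl = follower_id
                ld = i if fl == j else j
                to_partner = pos[ld] - pos[fl]
                phi = np.arctan2(to_partner[1], to_partner[0])
                # steering gain is linear in the social gain: at full
                # attraction the follower closes a fraction _W_MAX of its
                # heading error per reference frame (20 fps), i.e. aligns
                # within ~0.25 s; the exponent keeps the per-second gain
                # identical at other frame rates
                w = 1.0 - (1.0 - _W_MAX * cfg.attraction) ** (_FPS_REF * dt)
                heading[fl] = np.arctan2(
                    (1 - w) * np.sin(heading[fl]) + w * np.sin(phi),
                    (1 - w) * np.cos(heading[fl]) + w * np.cos(phi),
                )
        speed = base_speed[t].copy()
        # the social gain scales the whole behavioral effect of the state:
        # at attraction 0 the state is inert (independent walks), at 1 the
        # full slow-down social_speed_factor applies
        speed[social_member] *= 1.0 - cfg.attraction * (1.0 - cfg.social_speed_factor)

        step = (speed * dt)[:, None] * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        pos = pos + step
        out = (pos[:, 0] < 0) | (pos[:, 0] > W) | (pos[:, 1] < 0) | (pos[:, 1] > H)
        if out.any():
            idx = np.flatnonzero(out)
            pos[idx, 0] = _fold(pos[idx, 0], W)
            pos[idx, 1] = _fold(pos[idx, 1], H)
            # re-randomize heading on wall contact: point back into the
            # arena interior with fresh noise, avoiding corner trapping
            centre = np.array([W / 2, H / 2])
            for i in idx:
                inward = centre - pos[i]
                heading[i] = np.arctan2(inward[1], inward[0]) + rng.vonmises(
                    0.0, cfg.heading_concentration
                )
        xy[t] = pos

    if active_k >= 0:
        intervals[pairs[active_k]].append((onset, T))

    traj = TrajectorySet(xy=xy, fps=cfg.fps, arena=cfg.arena, group_id=f"sim-{cfg.seed}")
    truth = GroundTruth(
        social_intervals=intervals, followers=followers, turn_signs=turn_signs
    )
    return traj, truth


def simulate_sleep_track(
    cfg: SimConfig,
    duration_s: float = 24 * 3600.0,
    fps: float = 15.0,
    bout_schedule: Sequence[tuple[float, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrajectorySet, GroundTruth]:
    """Simulate a 24-h single-fish activity track for sleep scoring.

    Active/quiescent dwells alternate with exponential durations
    (``sleep_on_rate`` entering quiescence, ``sleep_off_rate`` leaving it);
    ``bout_schedule`` (list of quiescent ``(start_s, end_s)`` intervals)
    overrides the stochastic schedule for exact-recovery tests. Quiescent
    frames jitter around a rest point with ``quiescent_jitter_cm`` spread.
    Fully vectorized, so full-day tracks are cheap.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    T = int(round(duration_s * fps))
    W, H = cfg.arena.width, cfg.arena.height

    quiescent = np.zeros(T, dtype=bool)
    intervals: list[tuple[int, int]] = []
    if bout_schedule is not None:
        for s_s, e_s in bout_schedule:
            s, e = int(round(s_s * fps)), int(round(e_s * fps))
            if not 0 <= s < e <= T:
                raise ValueError(f"bout ({s_s}, {e_s}) s outside the recording")
            quiescent[s:e] = True
            intervals.append((s, e))
    elif cfg.sleep_on_rate > 0:
        t = 0.0
        asleep = False
        while t < duration_s:
            rate = cfg.sleep_off_rate if asleep else cfg.sleep_on_rate
            dwell = rng.exponential(1.0 / rate) if rate > 0 else duration_s
            t2 = min(t + dwell, duration_s)
            if asleep:
                s, e = int(round(t * fps)), int(round(t2 * fps))
                if e > s:
                    quiescent[s:e] = True
                    intervals.append((s, e))
            t = t2
            asleep = not asleep

    headings = np.cumsum(rng.vonmises(0.0, cfg.heading_concentration, size=T))
    speed = np.clip(rng.normal(cfg.mean_speed, cfg.sd_speed, size=T), 0.05, None)
    step = (speed / fps)[:, None] * np.column_stack(
        [np.cos(headings), np.sin(headings)]
    )
    step[quiescent] = 0.0
    start = np.array([rng.uniform(0, W), rng.uniform(0, H)])
    raw = start[None, :] + np.cumsum(step, axis=0)
    xy = np.empty((T, 1, 2))
    xy[:, 0, 0] = _fold(raw[:, 0], W)
    xy[:, 0, 1] = _fold(raw[:, 1], H)
    jitter = rng.normal(0.0, cfg.quiescent_jitter_cm, size=(T, 2))
    xy[quiescent, 0, :] += jitter[quiescent]
    np.clip(xy[..., 0], 0.0, W, out=xy[..., 0])
    np.clip(xy[..., 1], 0.0, H, out=xy[..., 1])

    traj = TrajectorySet(xy=xy, fps=fps, arena=cfg.arena, group_id=f"sleep-{cfg.seed}")
    truth = GroundTruth(
        social_intervals={}, followers={}, turn_signs=np.empty((0, 1)),
        sleep_intervals=intervals,
    )
    return traj, truth


def write_fixture(traj: TrajectorySet, out_dir: str | Path, stem: str = "traj") -> dict:
    """Write a trajectory as both tracker dialects plus a metadata sidecar.

    Returns the mapping of written paths. ``read_trajectories`` round-trips
    either file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "long": out_dir / f"{stem}_long.csv",
        "wide": out_dir / f"{stem}_wide.csv",
        "meta": out_dir / f"{stem}_meta.json",
    }
    write_trajectories(traj, paths["long"], dialect="long")
    write_trajectories(traj, paths["wide"], dialect="wide")
    traj.arena.to_json(paths["meta"], fps=traj.fps)
    return {k: str(v) for k, v in paths.items()}
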