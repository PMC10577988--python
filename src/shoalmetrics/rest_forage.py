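"""Sleep-bout segmentation, day/night activity summaries, and
vibration-attraction approach counting.

Sleep in Astyanax mexicanus tracking is scored behaviorally: a *sleep
bout* is a maximal run of immobility (speed below a threshold) lasting at
least ``min_bout`` seconds (default 60 s, with a 0.5 cm/s immobility
threshold, following the A. mexicanus sleep-assay literature). Day (ZT0-12)
and night (ZT12-24) statistics are reported separately under the standard
12:12 light:dark cycle; bouts spanning a light transition are split at the
boundary.

Vibration attraction behavior (VAB) counts approaches of the tracked point
into a circle around a vibrating-rod stimulus during a 3-min assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interaction import _runs
from .trajectory_io import TrajectorySet

__all__ = [
    "SleepParams",
    "SleepBout",
    "SleepSummary",
    "VabResult",
    "sleep_bouts",
    "vab_count",
]

_H12 = 12 * 3600.0  # seconds per light phase


@dataclass(frozen=True)
class SleepParams:
    """Immobility threshold (cm/s) and minimum bout length (s)."""

    immobility_speed: float = 0.5
    min_bout: float = 60.0

    def __post_init__(self) -> None:
        if self.min_bout <= 0 or self.immobility_speed <= 0:
            raise ValueError("immobility_speed and min_bout must be positive")


@dataclass(frozen=True)
class SleepBout:
    """One immobility bout (half-open frames) with its light phase."""

    fish: int
    start_frame: int
    end_frame: int
    phase: str  # "day" or "night"

    def duration_s(self, fps: float) -> float:
        return (self.end_frame - self.start_frame) / fps


@dataclass(frozen=True)
class PhaseSummary:
    sleep_min_per_h: float
    bout_count_per_h: float
    mean_bout_min: float
    hours_recorded: float


@dataclass(frozen=True)
class SleepSummary:
    """Per-fish day and night sleep statistics plus a 10-min binned series
    of sleep minutes per bin."""

    fish: int
    day: PhaseSummary
    night: PhaseSummary
    binned_sleep_min: np.ndarray  # sleep minutes per 10-min bin
    bin_s: float = 600.0


@dataclass(frozen=True)
class VabResult:
    """Approach count toward the vibrating-rod stimulus."""

    approach_count: int
    radius_cm: float
    assay_s: float


def _phase_of_frame(frame: int, zt0_frame: int, fps: float) -> str:
    zt_s = ((frame - zt0_frame) / fps) % (2 * _H12)
    return "day" if zt_s < _H12 else "night"


def _phase_boundaries(n_frames: int, zt0_frame: int, fps: float) -> np.ndarray:
    """Frame indices (within [1, n_frames)) where the lights switch."""
    half = _H12 * fps
    # boundaries occur at zt0_frame + k * half for integer k
    k_lo = int(np.floor((1 - zt0_frame) / half))
    k_hi = int(np.ceil((n_frames - zt0_frame) / half))
    b = zt0_frame + np.arange(k_lo, k_hi + 1) * half
    b = np.unique(np.round(b).astype(int))
    return b[(b > 0) & (b < n_frames)]


def sleep_bouts(
    traj: TrajectorySet,
    params: SleepParams | None = None,
    zt0_frame: int | None = None,
) -> tuple[list[SleepBout], list[SleepSummary]]:
    """Segment sleep bouts and summarize day/night sleep per fish.

    ``zt0_frame`` anchors Zeitgeber time: the frame index at which ZT0
    (lights-on) occurs, possibly negative if the recording started after
    lights-on. A run qualifies as sleep if its *total* immobile length is
    >= ``min_bout``; qualifying runs crossing a light transition are then
    split at the boundary so each piece is attributed to one phase.
    """
    params = params or SleepParams()
    if zt0_frame is None:
        raise ValueError("zt0_frame (lights-on anchor) is required")
    fps = traj.fps
    speeds = traj.speeds()  # (T-1, F)
    min_frames = int(np.ceil(params.min_bout * fps - 1e-9))
    boundaries = _phase_boundaries(speeds.shape[0], zt0_frame, fps)

    bouts: list[SleepBout] = []
    summaries: list[SleepSummary] = []
    n_speed = speeds.shape[0]
    for f in range(traj.n_fish):
        col = speeds[:, f]
        with np.errstate(invalid="ignore"):
            immobile = col < params.immobility_speed  # NaN -> False, breaks runs
        fish_bouts: list[SleepBout] = []
        for s, e in _runs(immobile):
            if e - s < min_frames:
                continue
            cuts = [s] + [int(b) for b in boundaries if s < b < e] + [e]
            for a, b in zip(cuts[:-1], cuts[1:]):
                fish_bouts.append(
                    SleepBout(
                        fish=f,
                        start_frame=int(a),
                        end_frame=int(b),
                        phase=_phase_of_frame(int(a), zt0_frame, fps),
                    )
                )
        bouts.extend(fish_bouts)

        # phase summaries
        frame_idx = np.arange(n_speed)
        zt_s = ((frame_idx - zt0_frame) / fps) % (2 * _H12)
        is_day = zt_s < _H12
        phase_summ = {}
        for phase, mask in (("day", is_day), ("night", ~is_day)):
            hours = float(mask.sum() / fps / 3600.0)
            pb = [b for b in fish_bouts if b.phase == phase]
            sleep_s = sum(b.duration_s(fps) for b in pb)
            phase_summ[phase] = PhaseSummary(
                sleep_min_per_h=(sleep_s / 60.0) / hours if hours else 0.0,
                bout_count_per_h=len(pb) / hours if hours else 0.0,
                mean_bout_min=(sleep_s / 60.0) / len(pb) if pb else 0.0,
                hours_recorded=hours,
            )

        # 10-min binned sleep minutes
        sleep_flag = np.zeros(n_speed, dtype=bool)
        for b in fish_bouts:
            sleep_flag[b.start_frame : b.end_frame] = True
        bin_frames = int(600 * fps)
        n_bins = int(np.ceil(n_speed / bin_frames))
        binned = np.array(
            [
                sleep_flag[k * bin_frames : (k + 1) * bin_frames].sum() / fps / 60.0
                for k in range(n_bins)
            ]
        )
        summaries.append(
            SleepSummary(
                fish=f,
                day=phase_summ["day"],
                night=phase_summ["night"],
                binned_sleep_min=binned,
            )
        )
    return bouts, summaries


def vab_count(
    traj: TrajectorySet,
    rod_xy: tuple[float, float],
    radius: float = 1.3,
    radius_unit: str = "cm",
    assay_s: float = 180.0,
    fish: int = 0,
) -> VabResult:
    """Count approaches into the circle of ``radius`` around the rod.

    An approach is an outside-to-inside transition of the tracked point;
    starting inside does not count until the fish has left and re-entered.
    The radius unit is configurable (``"cm"`` or ``"mm"``) because printed
    protocols differ; 1.3 cm is the physically plausible capture zone.
    Frames beyond ``assay_s`` are ignored; frames with missing tracking
    carry the last known inside/outside state forward.
    """
    rx, ry = rod_xy
    if not (0 <= rx <= traj.arena.width and 0 <= ry <= traj.arena.height):
        raise ValueError("rod position must lie inside the arena")
    r_cm = radius / 10.0 if radius_unit == "mm" else radius
    if radius_unit not in {"cm", "mm"}:
        raise ValueError("radius_unit must be 'cm' or 'mm'")
    n = min(int(round(assay_s * traj.fps)), traj.duration_frames)
    pos = traj.xy[:n, fish, :]
    dist = np.hypot(pos[:, 0] - rx, pos[:, 1] - ry)
    count = 0
    state: bool | None = None  # last known inside state
    for d in dist:
        if np.isnan(d):
            continue
        inside = bool(d <= r_cm)
        if state is False and inside:
            count += 1
        state = inside
    return VabResult(approach_count=count, radius_cm=r_cm, assay_s=assay_s)
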