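"""Swimming distance and the lateral turning-bias index.

Repetitive circling in cavefish is quantified by comparing the numbers of
left (anticlockwise, positive heading change) and right (clockwise,
negative) turns, sampled every ``window_frames`` frames (five frames =
0.25 s at 20 fps). The bias index is the larger count over the smaller,
ranging from 1 (balanced) to infinity (fully one-sided); the regularized
form ``(N_larger + 1) / (N_smaller + 1)`` stays finite for downstream
Gamma-family model fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory_io import TrajectorySet

__all__ = ["TurningRecord", "swim_distance", "turning_bias"]


@dataclass(frozen=True)
class TurningRecord:
    """Left/right turn counts and bias ratio for one fish."""

    fish: int
    n_left: int
    n_right: int
    ratio: float
    ratio_regularized: float
    window_frames: int = 5
    min_step: float = 0.1


def swim_distance(traj: TrajectorySet) -> np.ndarray:
    """Total path length in cm per fish over the assay window.

    Steps adjacent to a tracking gap contribute nothing (no positions are
    invented across gaps).
    """
    step = np.diff(traj.xy, axis=0)
    d = np.hypot(step[..., 0], step[..., 1])
    return np.nansum(d, axis=0)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(a + np.pi, 2 * np.pi) - np.pi
    out[out == -np.pi] = np.pi
    return out


def turning_bias(
    traj: TrajectorySet,
    window_frames: int = 5,
    min_step: float = 0.1,
    sliding: bool = False,
) -> list[TurningRecord]:
    """Left/right turn counts from block-wise headings, per fish.

    The trajectory is cut into blocks of ``window_frames`` frames
    (non-overlapping by default; ``sliding=True`` advances one frame at a
    time). Each block's heading is the direction of its net displacement;
    the signed wrapped angle between consecutive valid headings is one
    turn: positive = left (anticlockwise), negative = right. Blocks whose
    net displacement is below ``min_step`` cm, or which contain a tracking
    gap, are skipped (turns are only counted between consecutive valid
    blocks). A trajectory shorter than two blocks is an error.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    w = window_frames
    if traj.duration_frames < 2 * w + 1:
        raise ValueError(
            f"trajectory of {traj.duration_frames} frames is shorter than "
            f"two {w}-frame turning windows"
        )
    records: list[TurningRecord] = []
    step = 1 if sliding else w
    starts = np.arange(0, traj.duration_frames - w, step)
    for f in range(traj.n_fish):
        p0 = traj.xy[starts, f, :]
        p1 = traj.xy[starts + w, f, :]
        disp = p1 - p0
        norm = np.hypot(disp[:, 0], disp[:, 1])
        with np.errstate(invalid="ignore"):
            valid = ~np.isnan(norm) & (norm >= min_step)
        headings = np.arctan2(disp[:, 1], disp[:, 0])
        both = valid[1:] & valid[:-1]  # turns only between consecutive valid blocks
        turns = _wrap_angle(headings[1:] - headings[:-1])[both]
        n_left = int(np.sum(turns > 0))
        n_right = int(np.sum(turns < 0))
        lo, hi = min(n_left, n_right), max(n_left, n_right)
        if hi == 0:
            ratio = 1.0
        elif lo == 0:
            ratio = math.inf
        else:
            ratio = hi / lo
        records.append(
            TurningRecord(
                fish=f,
                n_left=n_left,
                n_right=n_right,
                ratio=ratio,
                ratio_regularized=(hi + 1) / (lo + 1),
                window_frames=w,
                min_step=min_step,
            )
        )
    return records
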