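"""Reading, validating, calibrating and windowing tracker trajectory tables.

Every downstream analysis in this package consumes a :class:`TrajectorySet`,
which fixes the conventions once:

* coordinates are in **cm**, origin at the arena's lower-left corner;
* the frame index is 0-based and windows are half-open ``[start, end)``;
* missing samples (tracking dropouts) are explicit ``NaN`` gaps and are
  *not* interpolated unless :func:`fill_gaps` is called.

Tracker exports (e.g. idTracker-style per-frame X-Y tables) come in two
dialects: *long* (one row per frame per fish: ``frame, fish_id, x, y``) and
*wide* (one row per frame: ``frame, x1, y1, x2, y2, ...``). Both are read
and written here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ArenaSpec",
    "TrajectorySet",
    "GapReport",
    "read_trajectories",
    "write_trajectories",
    "assay_window",
    "fill_gaps",
]

#: Default recording arena (cm), a 49.5 x 24.2 cm tank footprint.
DEFAULT_ARENA_W = 49.5
DEFAULT_ARENA_H = 24.2


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena geometry and optional pixel calibration.

    Parameters
    ----------
    width, height
        Arena footprint in cm.
    px_per_cm
        Pixel-to-cm scale of the raw coordinates; ``None`` means the file is
        already in cm.
    origin
        Corner convention label; only ``"lower-left"`` is produced by this
        package.
    """

    width: float = DEFAULT_ARENA_W
    height: float = DEFAULT_ARENA_H
    px_per_cm: float | None = None
    origin: str = "lower-left"

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("arena width and height must be positive")
        if self.px_per_cm is not None and not self.px_per_cm > 0:
            raise ValueError("px_per_cm must be positive when given")

    def to_json(self, path: str | Path, fps: float | None = None) -> None:
        d = {
            "width": self.width,
            "height": self.height,
            "px_per_cm": self.px_per_cm,
            "origin": self.origin,
        }
        if fps is not None:
            d["fps"] = fps
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArenaSpec":
        d = json.loads(Path(path).read_text())
        d.pop("fps", None)
        return cls(**d)


@dataclass(frozen=True)
class GapReport:
    """One contiguous run of missing samples for one fish."""

    fish: int
    start_frame: int
    length: int
    filled: bool = False


@dataclass(frozen=True)
class TrajectorySet:
    """Per-frame planar positions of all fish in one recorded group.

    ``xy`` has shape ``(duration_frames, n_fish, 2)`` in cm; missing samples
    are NaN in both coordinates.
    """

    xy: np.ndarray
    fps: float
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    group_id: str = ""
    gap_reports: tuple[GapReport, ...] = ()

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 3 or xy.shape[2] != 2:
            raise ValueError("xy must have shape (frames, fish, 2)")
        object.__setattr__(self, "xy", xy)
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.n_fish < 1:
            raise ValueError("need at least one fish")
        _check_inside(xy, self.arena)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_fish(self) -> int:
        return self.xy.shape[1]

    @property
    def duration_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def duration_s(self) -> float:
        return self.duration_frames / self.fps

    def speeds(self) -> np.ndarray:
        """Per-frame swimming speed in cm/s, shape ``(frames - 1, n_fish)``.

        Speed at index ``t`` is the displacement from frame ``t`` to
        ``t + 1`` times fps; NaN wherever either endpoint is missing.
        """
        step = np.diff(self.xy, axis=0)
        return np.hypot(step[..., 0], step[..., 1]) * self.fps

    def gaps(self) -> list[GapReport]:
        """Enumerate contiguous missing runs per fish."""
        out: list[GapReport] = []
        missing = np.isnan(self.xy).any(axis=2)  # (T, F)
        for f in range(self.n_fish):
            m = missing[:, f]
            edges = np.flatnonzero(np.diff(np.r_[0, m.view(np.int8), 0]))
            for s, e in zip(edges[::2], edges[1::2]):
                out.append(GapReport(fish=f, start_frame=int(s), length=int(e - s)))
        return out

    def to_dataframe(self, dialect: str = "long") -> pd.DataFrame:
        if dialect == "long":
            T, F, _ = self.xy.shape
            frames = np.repeat(np.arange(T), F)
            fish = np.tile(np.arange(F), T)
            flat = self.xy.reshape(T * F, 2)
            df = pd.DataFrame(
                {"frame": frames, "fish_id": fish, "x": flat[:, 0], "y": flat[:, 1]}
            )
            return df[~df[["x", "y"]].isna().all(axis=1)].reset_index(drop=True)
        if dialect == "wide":
            cols: dict[str, np.ndarray] = {"frame": np.arange(self.duration_frames)}
            for f in range(self.n_fish):
                cols[f"x{f + 1}"] = self.xy[:, f, 0]
                cols[f"y{f + 1}"] = self.xy[:, f, 1]
            return pd.DataFrame(cols)
        raise ValueError(f"unknown dialect {dialect!r}")


def _check_inside(xy: np.ndarray, arena: ArenaSpec, tol: float = 1e-6) -> None:
    x, y = xy[..., 0], xy[..., 1]
    with np.errstate(invalid="ignore"):
        bad = (
            (x < -tol)
            | (x > arena.width + tol)
            | (y < -tol)
            | (y > arena.height + tol)
        )
    if np.any(bad & ~np.isnan(x)):
        n = int(np.sum(bad & ~np.isnan(x)))
        raise ValueError(
            f"{n} coordinate sample(s) fall outside the "
            f"{arena.width} x {arena.height} cm arena"
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_trajectories(
    path: str | Path,
    fps: float,
    arena: ArenaSpec | None = None,
    group_id: str = "",
    out_of_arena_tol_cm: float = 0.5,
) -> TrajectorySet:
    """Read a tracker table (long or wide dialect, auto-detected).

    Coordinates are converted to cm with ``arena.px_per_cm`` when present.
    Missing frames or missing per-fish samples become explicit NaN gaps;
    duplicate ``(frame, fish_id)`` rows are rejected. Coordinates outside
    the arena by more than ``out_of_arena_tol_cm`` are rejected with a
    count; smaller excursions (tracker jitter at the wall) are clipped to
    the arena boundary.
    """
    arena = arena or ArenaSpec()
    df = _read_table(path)
    cols = set(df.columns)
    if {"frame", "fish_id", "x", "y"} <= cols:
        xy = _long_to_array(df)
    elif "frame" in cols and any(c.startswith("x") for c in cols - {"frame"}):
        xy = _wide_to_array(df)
    else:
        raise ValueError(
            "unrecognized trajectory dialect: need (frame, fish_id, x, y) "
            "or (frame, x1, y1, x2, y2, ...)"
        )
    if arena.px_per_cm is not None:
        xy = xy / arena.px_per_cm
    xy = _clip_to_arena(xy, arena, out_of_arena_tol_cm)
    return TrajectorySet(xy=xy, fps=fps, arena=arena, group_id=group_id)


def _long_to_array(df: pd.DataFrame) -> np.ndarray:
    if df.duplicated(subset=["frame", "fish_id"]).any():
        dups = df[df.duplicated(subset=["frame", "fish_id"], keep=False)]
        raise ValueError(
            f"duplicate (frame, fish_id) rows in input ({len(dups)} rows)"
        )
    frames = df["frame"].to_numpy(dtype=int)
    fish_ids = np.sort(df["fish_id"].unique())
    fish_index = {fid: i for i, fid in enumerate(fish_ids)}
    T = int(frames.max()) + 1
    xy = np.full((T, len(fish_ids), 2), np.nan)
    rows_f = np.array([fish_index[fid] for fid in df["fish_id"]])
    xy[frames, rows_f, 0] = df["x"].to_numpy(dtype=float)
    xy[frames, rows_f, 1] = df["y"].to_numpy(dtype=float)
    return xy


def _wide_to_array(df: pd.DataFrame) -> np.ndarray:
    n_fish = sum(1 for c in df.columns if c.startswith("x") and c != "x")
    frames = df["frame"].to_numpy(dtype=int)
    T = int(frames.max()) + 1
    xy = np.full((T, n_fish, 2), np.nan)
    for f in range(n_fish):
        xy[frames, f, 0] = df[f"x{f + 1}"].to_numpy(dtype=float)
        xy[frames, f, 1] = df[f"y{f + 1}"].to_numpy(dtype=float)
    return xy


def _clip_to_arena(xy: np.ndarray, arena: ArenaSpec, tol_cm: float) -> np.ndarray:
    x, y = xy[..., 0], xy[..., 1]
    with np.errstate(invalid="ignore"):
        far = (
            (x < -tol_cm)
            | (x > arena.width + tol_cm)
            | (y < -tol_cm)
            | (y > arena.height + tol_cm)
        ) & ~np.isnan(x)
    if far.any():
        raise ValueError(
            f"{int(far.sum())} sample(s) lie more than {tol_cm} cm outside "
            f"the {arena.width} x {arena.height} cm arena; check calibration"
        )
    out = xy.copy()
    out[..., 0] = np.clip(out[..., 0], 0.0, arena.width)
    out[..., 1] = np.clip(out[..., 1], 0.0, arena.height)
    return out


def write_trajectories(
    traj: TrajectorySet, path: str | Path, dialect: str = "long"
) -> None:
    """Write a trajectory table; see :func:`read_trajectories` for dialects."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    traj.to_dataframe(dialect).to_csv(path, sep=sep, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# windowing and gap handling


def assay_window(
    traj: TrajectorySet, discard_head_s: float, keep_s: float
) -> TrajectorySet:
    """Trailing analysis window: drop at least the first ``discard_head_s``
    seconds and keep the final ``keep_s`` seconds, frame indices re-zeroed.

    The standard group assay records 6 min and analyzes the last 5 min.
    """
    if discard_head_s < 0 or keep_s <= 0:
        raise ValueError("discard_head_s must be >= 0 and keep_s > 0")
    keep_f = int(round(keep_s * traj.fps))
    discard_f = int(round(discard_head_s * traj.fps))
    if discard_f + keep_f > traj.duration_frames:
        raise ValueError(
            f"window of {discard_head_s}+{keep_s} s exceeds the "
            f"{traj.duration_s:.1f} s recording"
        )
    start = traj.duration_frames - keep_f
    return replace(traj, xy=traj.xy[start:], gap_reports=())


def fill_gaps(traj: TrajectorySet, max_gap_frames: int) -> TrajectorySet:
    """Linearly interpolate missing runs of length <= ``max_gap_frames``.

    Longer gaps, and gaps touching either end of the recording, are left
    missing. A per-gap report (filled or not) is attached to the result.
    ``max_gap_frames = 0`` is the identity and is the package default policy:
    downstream metrics treat missing frames as run-breakers rather than
    inventing positions.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if max_gap_frames == 0:
        return replace(traj, gap_reports=tuple(traj.gaps()))
    xy = traj.xy.copy()
    reports: list[GapReport] = []
    for g in traj.gaps():
        interior = g.start_frame > 0 and g.start_frame + g.length < traj.duration_frames
        fill = interior and g.length <= max_gap_frames
        if fill:
            s, e = g.start_frame, g.start_frame + g.length
            t = np.arange(s, e)
            for k in range(2):
                xy[t, g.fish, k] = np.interp(
                    t, [s - 1, e], [xy[s - 1, g.fish, k], xy[e, g.fish, k]]
                )
        reports.append(replace(g, filled=fill))
    return replace(traj, xy=xy, gap_reports=tuple(reports))
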