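import numpy as np
import pytest
from hypothesis import settings

from shoalmetrics.trajectory_io import ArenaSpec, TrajectorySet

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec()


def make_traj(xy, fps=20.0, arena=None, **kw) -> TrajectorySet:
    """Build a TrajectorySet from a (frames, fish, 2) array-like."""
    xy = np.asarray(xy, dtype=float)
    if arena is None:
        w = max(np.nanmax(xy[..., 0], initial=1.0) + 1, 49.5)
        h = max(np.nanmax(xy[..., 1], initial=1.0) + 1, 24.2)
        arena = ArenaSpec(width=float(w), height=float(h))
    return TrajectorySet(xy=xy, fps=fps, arena=arena, **kw)


def straight_line(n_frames, speed_cm_s, fps=20.0, y=5.0, x0=1.0):
    """Single fish moving at constant speed along +x."""
    x = x0 + np.arange(n_frames) * speed_cm_s / fps
    xy = np.stack([x, np.full(n_frames, y)], axis=1)[:, None, :]
    return xy
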