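"""End-to-end assay pipeline: read or simulate, window, detect, score,
summarize, and write a reproducible report bundle.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same manifest reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .interaction import (
    InteractionCriteria,
    detect_events,
    event_raster,
    events_to_frame,
    interaction_scores,
    speed_profile,
)
from .locomotion import swim_distance, turning_bias
from .synthetic_data import SimConfig, simulate_group, write_fixture
from .trajectory_io import ArenaSpec, assay_window, read_trajectories

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - report with stage context
                raise PipelineError(name, e) from e

        return wrapped

    return deco


@_stage("load")
def _load_groups(config: dict[str, Any]) -> list:
    arena = ArenaSpec(
        width=config.get("arena_w", 49.5),
        height=config.get("arena_h", 24.2),
        px_per_cm=config.get("px_per_cm"),
    )
    fps = config.get("fps", 20.0)
    if "simulate" in config:
        sim = dict(config["simulate"])
        n_groups = int(sim.pop("n_groups", 1))
        base_seed = int(sim.pop("seed", config.get("seed", 0)))
        cfg = SimConfig(arena=arena, fps=fps, **sim, seed=base_seed)
        groups = []
        for g in range(n_groups):
            traj, _ = simulate_group(
                cfg, rng=np.random.default_rng(base_seed + g)
            )
            groups.append(traj)
        return groups
    paths = sorted(Path(config["input_dir"]).glob(config.get("pattern", "*.csv")))
    if not paths:
        raise FileNotFoundError(
            f"no trajectory files in {config['input_dir']!r}"
        )
    return [
        read_trajectories(p, fps=fps, arena=arena, group_id=p.stem) for p in paths
    ]


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the standard assay pipeline and write a report bundle.

    ``config`` names either a simulation scenario (``simulate: {...}``)
    or an input directory of trajectory tables, plus windowing and
    criterion settings. Outputs: per-group metrics TSV, events TSV, and a
    manifest JSON recording versions, seed and parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = _load_groups(config)

    crit = InteractionCriteria(
        max_distance=config.get("max_distance", 5.0),
        min_duration=config.get("min_duration", 4.0),
    )
    discard = config.get("discard_head_s", 60.0)
    keep = config.get("keep_s", 300.0)

    metrics_rows = []
    event_frames = []
    for traj in groups:
        try:
            win = assay_window(traj, discard, keep) if keep else traj
            events = detect_events(win, crit)
            scores = interaction_scores(events, win)
            dist = swim_distance(win)
            turning = turning_bias(win, config.get("turn_window", 5))
            profiles = speed_profile(win, events, config.get("window_s", 4.0))
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"metrics[{traj.group_id}]", e) from e
        ev = events_to_frame(events, win.fps)
        ev.insert(0, "group_id", traj.group_id)
        event_frames.append(ev)
        for f in range(win.n_fish):
            metrics_rows.append(
                {
                    "group_id": traj.group_id,
                    "fish": f,
                    "interaction_duration_s": scores.duration_s,
                    "interaction_count": scores.count,
                    "swim_distance_cm": float(dist[f]),
                    "turning_ratio": turning[f].ratio,
                    "turning_ratio_regularized": turning[f].ratio_regularized,
                    "during_speed": profiles[f].during_mean,
                    "out_speed": profiles[f].out_of_event_mean,
                }
            )

    metrics = pd.DataFrame(metrics_rows)
    events_all = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=["group_id", "pair", "start_s", "end_s", "duration_s"])
    )
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    events_all.to_csv(out / "events.tsv", sep="\t", index=False)

    manifest = {
        "shoalmetrics_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {k: v for k, v in config.items()},
        "n_groups": len(groups),
        "criteria": asdict(crit),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "metrics": metrics,
        "events": events_all,
        "manifest": manifest,
    }
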