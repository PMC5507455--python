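"""File formats: trajectory CSV, event/turn CSV, summary and manifest JSON.

Trajectory CSV schema (one row per frame, header required)::

    frame,t,head_x,head_y,mid_x,mid_y,tail_x,tail_y,cm_x,cm_y

Coordinates are pixels. When the recording uses image coordinates
(y growing downward), set ``y_axis: "down"`` in the config and the
reader flips the y axis to the Cartesian arena frame on read. Frame
indices are 0-based; all event intervals are inclusive of both ends.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import __version__
from .classification import TrialResult
from .config import Config
from .kinematics import Trajectory, TrajectoryError

TRAJECTORY_COLUMNS = ["frame", "t", "head_x", "head_y", "mid_x", "mid_y",
                      "tail_x", "tail_y", "cm_x", "cm_y"]


class ParseError(ValueError):
    """Malformed input file."""


def read_trajectory_csv(path: str | Path, cfg: Config | None = None) -> Trajectory:
    """Read and validate one trial's trajectory.

    Raises :class:`ParseError` naming the offending row for missing
    columns, non-monotone frame indices or non-finite coordinates.
    """
    cfg = cfg or Config()
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    frames = df["frame"].to_numpy()
    bad = np.flatnonzero(np.diff(frames) <= 0)
    if bad.size:
        # offending row: header is line 1, data row i is line i + 2
        raise ParseError(
            f"{path.name}: frame index not strictly increasing at row {bad[0] + 3}")
    coords = df[TRAJECTORY_COLUMNS[2:]].to_numpy(dtype=float)
    nonfinite = ~np.isfinite(coords).all(axis=1)
    if nonfinite.any():
        row = int(np.flatnonzero(nonfinite)[0])
        raise ParseError(f"{path.name}: non-finite coordinates at row {row + 2}")
    ysign = -1.0 if cfg.y_axis == "down" else 1.0

    def pts(prefix: str) -> np.ndarray:
        return np.column_stack([df[f"{prefix}_x"].to_numpy(dtype=float),
                                ysign * df[f"{prefix}_y"].to_numpy(dtype=float)])

    try:
        return Trajectory(frame_index=frames, head=pts("head"), mid=pts("mid"),
                          tail=pts("tail"), centroid=pts("cm"),
                          frame_rate=cfg.frame_rate, px_per_mm=cfg.px_per_mm,
                          trial_id=path.stem)
    except TrajectoryError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_trajectory_csv(path: str | Path, traj: Trajectory,
                         cfg: Config | None = None) -> None:
    cfg = cfg or Config()
    ysign = -1.0 if cfg.y_axis == "down" else 1.0
    df = pd.DataFrame({
        "frame": traj.frame_index,
        "t": traj.t,
        "head_x": traj.head[:, 0], "head_y": ysign * traj.head[:, 1],
        "mid_x": traj.mid[:, 0], "mid_y": ysign * traj.mid[:, 1],
        "tail_x": traj.tail[:, 0], "tail_y": ysign * traj.tail[:, 1],
        "cm_x": traj.centroid[:, 0], "cm_y": ysign * traj.centroid[:, 1],
    })
    df.to_csv(path, index=False, float_format="%.6f")


def events_frame(trials: Iterable[TrialResult]) -> pd.DataFrame:
    """One row per head cast across trials (0-based frames, inclusive)."""
    rows = []
    for trial in trials:
        for c in trial.casts:
            rows.append({
                "trial_id": trial.trial_id, "stop_index": c.stop_index,
                "ordinal": c.ordinal, "start_frame": c.start_frame,
                "peak_frame": c.peak_frame, "end_frame": c.end_frame,
                "amplitude_rad_s": c.amplitude, "direction": c.direction,
                "acceptance": {True: "accepted", False: "rejected", None: ""}[c.accepted],
                "success": c.success,
            })
    return pd.DataFrame(rows, columns=[
        "trial_id", "stop_index", "ordinal", "start_frame", "peak_frame",
        "end_frame", "amplitude_rad_s", "direction", "acceptance", "success"])


def turns_frame(trials: Iterable[TrialResult]) -> pd.DataFrame:
    """One row per turn event across trials."""
    rows = []
    for trial in trials:
        for t in trial.turns:
            rows.append({
                "trial_id": trial.trial_id, "stop_index": t.stop_index,
                "stop_start_frame": t.stop_start_frame,
                "turn_peak_frame": t.turn_peak_frame,
                "n_casts": t.n_casts, "kind": t.kind.value,
                "init_distance_px": t.init_distance,
                "light_related": t.light_related, "success": t.success,
            })
    return pd.DataFrame(rows, columns=[
        "trial_id", "stop_index", "stop_start_frame", "turn_peak_frame",
        "n_casts", "kind", "init_distance_px", "light_related", "success"])


def write_summary_json(path: str | Path, summary: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(path: str | Path, cfg: Config, inputs: list[str],
                   counts: dict[str, int], seed: int | None = None,
                   warnings: list[str] | None = None) -> None:
    manifest = {
        "software": "lightcast",
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": sorted(inputs),
        "seed": seed,
        "event_counts": counts,
        "warnings": warnings or [],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
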