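"""Analysis configuration: thresholds, smoothing windows, and calibration.

All thresholds follow the standard behavioral definitions for larval
light-spot phototaxis: a stop period is sub-threshold tail speed
(0.21 mm/s = 2.5 px/s at 11.94 px/mm), a head cast is a supra-threshold
headomega peak (20.05 deg/s = 0.35 rad/s), success of light avoidance is
judged against the light-spot edge expanded 10 px for scatter, and turns
are light-related only within 20 px (outside) / 50 px (inside) of the
edge and before 5 s of cumulative light exposure.

Angles are radians and times seconds throughout the library; degrees and
pixel/mm conversions appear only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass(frozen=True)
class Config:
    """Thresholds and numerical settings for the full pipeline.

    Parameters
    ----------
    frame_rate : float
        Video frame rate, Hz. Default 60 fps.
    px_per_mm : float
        Spatial calibration. Default 11.94 px/mm.
    tailspeed_stop_thresh : float
        Stop-period tail-speed threshold, mm/s.
    headomega_peak_thresh : float
        Head-cast detection threshold on |headomega|, rad/s.
    bodyomega_turn_thresh : float
        Body-turn detection threshold on |bodyomega|, rad/s (the source
        analysis states no separate value; symmetric with the head
        threshold by design).
    min_stop_duration, max_stop_gap : float
        Seconds. Sub-threshold runs shorter than ``min_stop_duration``
        are discarded; above-threshold gaps up to ``max_stop_gap`` are
        merged into one stop period.
    peak_delta : float
        Commit delta of the peak detector, rad/s.
    smoothing_window : int
        Moving-average window (frames, odd) applied to headomega,
        bodyomega and tailspeed.
    position_smoothing_window : int
        Moving-average window (frames, odd) applied to tracked point
        coordinates before any derivative, to suppress tracking jitter.
    speed_stencil, angle_stencil : int
        Half-width k (frames) of the symmetric central difference
        (x[i+k] - x[i-k]) / (2k dt) used for speeds and angular speeds.
    straighten_drop : float
        Net |headtheta| decrease (rad) over a candidate cast span that
        classifies the headomega peak as body straightening, not a cast.
    success_margin_px : float
        Outward expansion of the spot edge when judging success and
        light exposure (light scatter allowance).
    relate_out_px, relate_in_px : float
        Light-relatedness windows for turns initiated outside/inside
        the nominal spot edge.
    exposure_cutoff_s : float
        Turns initiated after this much cumulative head-in-light time
        are not light-related (light adaptation guard).
    max_gap_frames : int
        Longest run of invalid frames repaired by linear interpolation;
        longer gaps split the trajectory.
    y_axis : str
        ``"up"`` if input coordinates are Cartesian, ``"down"`` if they
        are image coordinates (y flipped on read).
    """

    frame_rate: float = 60.0
    px_per_mm: float = 11.94
    tailspeed_stop_thresh: float = 0.21
    headomega_peak_thresh: float = 0.35
    bodyomega_turn_thresh: float = 0.35
    min_stop_duration: float = 0.25
    max_stop_gap: float = 0.15
    peak_delta: float = 0.25
    smoothing_window: int = 9
    position_smoothing_window: int = 9
    speed_stencil: int = 10
    angle_stencil: int = 8
    straighten_drop: float = 0.05
    success_margin_px: float = 10.0
    relate_out_px: float = 20.0
    relate_in_px: float = 50.0
    exposure_cutoff_s: float = 5.0
    max_gap_frames: int = 3
    y_axis: str = "up"

    def __post_init__(self) -> None:
        positive = (
            "frame_rate", "px_per_mm", "tailspeed_stop_thresh",
            "headomega_peak_thresh", "bodyomega_turn_thresh",
            "min_stop_duration", "max_stop_gap", "peak_delta",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("smoothing_window", "position_smoothing_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ConfigError(f"{name} must be a positive odd frame count, got {w}")
        for name in ("speed_stencil", "angle_stencil"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.success_margin_px < 0:
            raise ConfigError("success_margin_px must be >= 0")
        if self.y_axis not in ("up", "down"):
            raise ConfigError(f"y_axis must be 'up' or 'down', got {self.y_axis!r}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
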