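"""Light-spot geometry: signed distance, membership, exposure.

The assay projects a 2-cm-diameter light spot onto the agar plate
(radius 10 mm = 119.4 px at 11.94 px/mm). Distances from the larval
head to the nearest point of the spot edge are signed: positive outside
the spot, negative inside. Because the larva can sense scattered light
just beyond the nominal edge, success of light avoidance is judged
against the edge expanded outward by 10 px (~0.84 mm), and the same
expanded region defines "in light" for cumulative exposure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
from scipy.signal import savgol_filter
from shapely.geometry import Point, Polygon

from .config import ConfigError


class ArenaError(ValueError):
    """Invalid light-spot geometry."""


@dataclass(frozen=True)
class LightSpot:
    """Circular (canonical) or polygonal light region, px units.

    ``expansion`` records how far the boundary has been offset outward
    from the nominal spot (0 for the nominal geometry).
    """

    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: tuple[tuple[float, float], ...] | None = None
    expansion: float = 0.0

    def __post_init__(self) -> None:
        if self.radius is not None:
            if self.center is None:
                raise ArenaError("circle spot needs a center")
            if self.radius <= 0:
                raise ArenaError("circle radius must be > 0")
        elif self.vertices is not None:
            poly = Polygon(self.vertices)
            if len(self.vertices) < 3 or not poly.is_valid:
                raise ArenaError("polygon spot must be simple and closed")
        else:
            raise ArenaError("spot needs a radius or vertices")

    @property
    def is_circle(self) -> bool:
        return self.radius is not None

    @classmethod
    def circle(cls, center: tuple[float, float], radius: float) -> "LightSpot":
        return cls(center=tuple(center), radius=float(radius))

    @classmethod
    def nominal(cls, center: tuple[float, float] = (0.0, 0.0),
                px_per_mm: float = 11.94, diameter_mm: float = 20.0) -> "LightSpot":
        """The standard 2-cm spot at the given calibration."""
        return cls.circle(center, diameter_mm / 2.0 * px_per_mm)

    @classmethod
    def polygon(cls, vertices) -> "LightSpot":
        return cls(vertices=tuple(map(tuple, vertices)))

    def _shape(self) -> Polygon:
        return Polygon(self.vertices)

    def to_dict(self) -> dict[str, Any]:
        if self.is_circle:
            return {"shape": "circle", "center_px": list(self.center),
                    "radius_px": self.radius}
        return {"shape": "polygon",
                "vertices_px": [list(v) for v in self.vertices]}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "LightSpot":
        if d.get("shape") == "circle":
            return cls.circle(tuple(d["center_px"]), d["radius_px"])
        if d.get("shape") == "polygon":
            return cls.polygon(d["vertices_px"])
        raise ArenaError(f"unknown spot shape {d.get('shape')!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "LightSpot":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def signed_distance(p, spot: LightSpot) -> float | np.ndarray:
    """Euclidean distance from p to the spot boundary, signed.

    Positive outside the light region, negative inside, 0 on the
    boundary. Accepts a single (2,) point or an (n, 2) array.
    """
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    if spot.is_circle:
        r = np.hypot(pts[:, 0] - spot.center[0], pts[:, 1] - spot.center[1])
        d = r - spot.radius
    else:
        poly = spot._shape()
        boundary = poly.exterior
        d = np.array([
            boundary.distance(Point(xy)) * (-1.0 if poly.contains(Point(xy)) else 1.0)
            for xy in pts])
    return d if len(d) > 1 else float(d[0])


def expand(spot: LightSpot, margin: float) -> LightSpot:
    """Offset the spot boundary outward by ``margin`` px.

    Circles grow in radius; polygons take the Minkowski sum with a disc
    (round joins). For circles, signed_distance to the expanded spot is
    exactly signed_distance to the original minus margin.
    """
    if margin < 0:
        raise ArenaError("negative expansion margins are not allowed")
    if margin == 0:
        return spot
    if spot.is_circle:
        return LightSpot(center=spot.center, radius=spot.radius + margin,
                         expansion=spot.expansion + margin)
    grown = spot._shape().buffer(margin, quad_segs=64)
    return LightSpot(vertices=tuple(grown.exterior.coords[:-1]),
                     expansion=spot.expansion + margin)


def head_in_light(p, spot: LightSpot, margin: float = 0.0):
    """True iff p is strictly inside the margin-expanded light region.

    A point exactly on the (expanded) boundary counts as out of light.
    """
    return signed_distance(p, expand(spot, margin)) < 0


def cumulative_exposure(traj, spot: LightSpot, margin: float = 0.0) -> np.ndarray:
    """Cumulative seconds of head-in-light per frame, from trial start.

    Nondecreasing; each frame with the head inside the margin-expanded
    spot contributes 1/frame_rate. Exposure never resets on exit
    ("total" exposure time).
    """
    inside = np.atleast_1d(head_in_light(traj.head, spot, margin))
    return np.cumsum(inside.astype(float)) / traj.frame_rate


def smooth_spot_edge(boundary: np.ndarray, order: int = 12, window: int | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing of an ordered closed-boundary point list.

    Both coordinate sequences are filtered with a polynomial of the
    given order (default 12, the conventional edge treatment)
    under periodic (wrap) boundary handling; the vertex count is
    preserved. ``window`` defaults to the smallest odd count above
    ``order`` + 2 that the boundary supports.
    """
    pts = np.asarray(boundary, dtype=float)
    n = len(pts)
    if window is None:
        window = min(order + 3 + ((order + 3) % 2 == 0), n - (n % 2 == 0))
    if window % 2 == 0 or window <= order:
        raise ConfigError("window must be odd and greater than the polynomial order")
    if window > n:
        raise ConfigError(f"window {window} exceeds boundary point count {n}")
    out = np.column_stack([
        savgol_filter(pts[:, 0], window, order, mode="wrap"),
        savgol_filter(pts[:, 1], window, order, mode="wrap"),
    ])
    return out
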