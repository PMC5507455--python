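"""Per-frame kinematic signals from tracked larval body points.

The tracker supplies head, midpoint, tail and centroid coordinates per
frame. From these we derive the signals the behavioral definitions are
built on:

* ``headtheta`` — signed angle between the head-midpoint axis and the
  midpoint-tail axis (the head-sweep angle; 0 for a straight body),
* ``headomega`` — its angular speed (head-cast speed indicator),
* ``bodytheta`` — orientation of the midpoint-tail axis in the arena
  frame, ``bodyomega`` — its angular speed (turn indicator),
* ``headspeed``/``midspeed``/``tailspeed``/``cmspeed`` — point speeds
  in mm/s (``tailspeed`` defines stop periods).

headomega, bodyomega and tailspeed are smoothed with a centered moving
average, and point coordinates are smoothed before differentiation to
keep frame-to-frame tracking jitter out of the derivatives. Angles are
phase-unwrapped before differencing so the +/-pi wrap never produces
spurious angular speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config, ConfigError


class TrajectoryError(ValueError):
    """Trajectory too short or structurally invalid."""


@dataclass
class Trajectory:
    """Calibrated body-point time series for one trial.

    Coordinates are pixels in a y-up Cartesian arena frame; ``frame_index``
    is strictly increasing and ``t = frame_index / frame_rate``.
    """

    frame_index: np.ndarray  # (n,) int
    head: np.ndarray         # (n, 2) px
    mid: np.ndarray          # (n, 2) px
    tail: np.ndarray         # (n, 2) px
    centroid: np.ndarray     # (n, 2) px
    frame_rate: float = 60.0
    px_per_mm: float = 11.94
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        for name in ("head", "mid", "tail", "centroid"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise TrajectoryError(f"{name} must be an (n, 2) array")
            setattr(self, name, arr)
        n = len(self.frame_index)
        if n < 2:
            raise TrajectoryError("trajectory needs at least 2 frames")
        if any(len(getattr(self, k)) != n for k in ("head", "mid", "tail", "centroid")):
            raise TrajectoryError("all point series must have one row per frame")
        if self.frame_rate <= 0 or self.px_per_mm <= 0:
            raise TrajectoryError("frame_rate and px_per_mm must be > 0")
        if np.any(np.diff(self.frame_index) <= 0):
            raise TrajectoryError("frame_index must be strictly increasing")
        if np.any(self.frame_index < 0):
            raise TrajectoryError("frame_index must be nonnegative")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def t(self) -> np.ndarray:
        return self.frame_index / self.frame_rate

    @property
    def duration(self) -> float:
        return (self.frame_index[-1] - self.frame_index[0]) / self.frame_rate


@dataclass
class KinematicSeries:
    """Derived per-frame signals; one value per trajectory frame.

    ``valid`` flags frames whose geometry was non-degenerate (distinct
    body points); invalid frames carry interpolated values when the gap
    was short enough to repair.
    """

    headspeed: np.ndarray
    midspeed: np.ndarray
    tailspeed: np.ndarray
    cmspeed: np.ndarray
    headtheta: np.ndarray
    headomega: np.ndarray
    bodytheta: np.ndarray
    bodyomega: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.headspeed), dtype=bool)


def _signed_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle from vector u to vector v, in (-pi, pi], CCW positive."""
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return np.arctan2(cross, dot)


def compute_headtheta(head: np.ndarray, mid: np.ndarray, tail: np.ndarray) -> np.ndarray:
    """Signed angle from the tail->mid direction to the mid->head direction.

    Zero for a straight body, positive for a counter-clockwise head
    deviation in the (y-up) arena frame, in (-pi, pi]. Frames with
    coincident points yield NaN rather than raising.
    """
    head = np.atleast_2d(np.asarray(head, dtype=float))
    mid = np.atleast_2d(np.asarray(mid, dtype=float))
    tail = np.atleast_2d(np.asarray(tail, dtype=float))
    u = mid - tail
    v = head - mid
    theta = _signed_angle(u, v)
    bad = (np.linalg.norm(u, axis=-1) == 0) | (np.linalg.norm(v, axis=-1) == 0)
    theta = np.where(bad, np.nan, theta)
    return theta if theta.size > 1 else float(theta[0])


def compute_bodytheta(mid: np.ndarray, tail: np.ndarray) -> np.ndarray:
    """Angle of the tail->mid axis from the +x (horizontal) arena axis.

    Returned wrapped to (-pi, pi]; unwrapping across frames is the job
    of :func:`differentiate_angle`. Coincident mid/tail yields NaN.
    """
    mid = np.atleast_2d(np.asarray(mid, dtype=float))
    tail = np.atleast_2d(np.asarray(tail, dtype=float))
    u = mid - tail
    theta = np.arctan2(u[..., 1], u[..., 0])
    theta = np.where(np.linalg.norm(u, axis=-1) == 0, np.nan, theta)
    return theta if theta.size > 1 else float(theta[0])


def _central_diff(x: np.ndarray, dt: float, k: int) -> np.ndarray:
    """Symmetric central difference (x[i+k] - x[i-k]) / (2k dt).

    Edges fall back to progressively narrower symmetric stencils and,
    at the first/last frame, one-sided differences, so the output has
    the input length. Exact for linear series at every frame.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise TrajectoryError("need at least 2 frames to differentiate")
    k = min(k, n - 1)
    out = np.empty_like(x)
    # interior: widest symmetric stencil that fits
    for j in range(1, k + 1):
        sl = slice(j, n - j)
        if j == k:
            out[sl] = (x[2 * j:] - x[: n - 2 * j]) / (2 * j * dt)
        else:
            # frames exactly j from an edge use the +/-j stencil
            out[j] = (x[2 * j] - x[0]) / (2 * j * dt)
            out[n - 1 - j] = (x[n - 1] - x[n - 1 - 2 * j]) / (2 * j * dt)
    out[0] = (x[1] - x[0]) / dt
    out[-1] = (x[-1] - x[-2]) / dt
    return out


def compute_speed(points: np.ndarray, frame_rate: float, px_per_mm: float,
                  stencil: int = 1) -> np.ndarray:
    """Per-frame speed (mm/s) of a 2D point series sampled at frame_rate.

    Interior frames use a symmetric central difference of half-width
    ``stencil`` frames; endpoints use one-sided differences. Output
    length equals input length and all values are nonnegative.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise TrajectoryError("points must be an (n>=2, 2) array")
    dt = 1.0 / frame_rate
    vx = _central_diff(pts[:, 0], dt, stencil)
    vy = _central_diff(pts[:, 1], dt, stencil)
    return np.hypot(vx, vy) / px_per_mm


def differentiate_angle(theta: np.ndarray, frame_rate: float, stencil: int = 1) -> np.ndarray:
    """Angular speed (rad/s) of an angle series.

    The series is phase-unwrapped first so crossings of the +/-pi wrap
    do not produce 2*pi jumps; differencing then follows
    :func:`compute_speed`'s scheme (signed, not rectified).
    """
    theta = np.asarray(theta, dtype=float)
    if len(theta) < 2:
        raise TrajectoryError("need at least 2 frames to differentiate")
    return _central_diff(np.unwrap(theta), 1.0 / frame_rate, stencil)


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with an odd window; edges shrink symmetrically.

    window=1 is the identity. NaNs propagate (repair gaps first).
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 1, got {window}")
    if window > len(x):
        raise ConfigError(f"window {window} exceeds series length {len(x)}")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    # shrink to the symmetric window that fits at the edges
    reach = np.minimum(idx - lo, hi - idx)
    lo = idx - reach
    hi = idx + reach
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _fill_short_gaps(x: np.ndarray, invalid: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate invalid runs of length <= max_gap.

    Returns (filled series, mask of still-invalid frames).
    """
    x = x.astype(float).copy()
    still = invalid.copy()
    n = len(x)
    i = 0
    while i < n:
        if not invalid[i]:
            i += 1
            continue
        j = i
        while j < n and invalid[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            x[i:j] = np.interp(np.arange(i, j), [i - 1, j], [x[i - 1], x[j]])
            still[i:j] = False
        i = j
    return x, still


def split_on_invalid(traj: Trajectory, invalid: np.ndarray, max_gap: int) -> list[Trajectory]:
    """Split a trajectory at invalid runs longer than ``max_gap`` frames.

    Returned segments keep the original global frame indices and drop
    the offending frames; segments shorter than 2 frames are discarded.
    """
    n = traj.n_frames
    keep = ~invalid
    segments: list[Trajectory] = []
    i = 0
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n:
            if keep[j]:
                j += 1
                continue
            g = j
            while g < n and not keep[g]:
                g += 1
            if g - j <= max_gap:
                j = g
            else:
                break
        sl = slice(i, j)
        if j - i >= 2:
            segments.append(Trajectory(
                frame_index=traj.frame_index[sl], head=traj.head[sl],
                mid=traj.mid[sl], tail=traj.tail[sl], centroid=traj.centroid[sl],
                frame_rate=traj.frame_rate, px_per_mm=traj.px_per_mm,
                trial_id=traj.trial_id))
        i = j
        while i < n and not keep[i]:
            i += 1
    return segments


def _smooth_points(pts: np.ndarray, window: int) -> np.ndarray:
    return np.column_stack([moving_average(pts[:, 0], window),
                            moving_average(pts[:, 1], window)])


def compute_kinematics(traj: Trajectory, cfg: Config | None = None) -> KinematicSeries:
    """Assemble all kinematic series for one trajectory.

    Point coordinates are moving-average smoothed before any derivative
    (tracking-jitter suppression); headomega, bodyomega and tailspeed
    are additionally smoothed with ``cfg.smoothing_window``, matching
    the signals the behavioral thresholds are applied to. Frames with
    degenerate geometry are flagged invalid and short invalid gaps in
    the angle series are interpolated before differentiation.
    """
    cfg = cfg or Config()
    wpos = min(cfg.position_smoothing_window,
               traj.n_frames if traj.n_frames % 2 == 1 else traj.n_frames - 1)
    head = _smooth_points(traj.head, wpos)
    mid = _smooth_points(traj.mid, wpos)
    tail = _smooth_points(traj.tail, wpos)
    cm = _smooth_points(traj.centroid, wpos)

    headtheta = np.atleast_1d(compute_headtheta(head, mid, tail))
    bodytheta = np.atleast_1d(compute_bodytheta(mid, tail))
    invalid = ~(np.isfinite(headtheta) & np.isfinite(bodytheta))
    headtheta_f, still = _fill_short_gaps(headtheta, invalid, cfg.max_gap_frames)
    bodytheta_f, _ = _fill_short_gaps(bodytheta, invalid, cfg.max_gap_frames)
    if np.any(still):
        raise TrajectoryError(
            "trajectory contains degenerate gaps longer than "
            f"{cfg.max_gap_frames} frames; split it first (see split_on_invalid)")

    fs, ppmm = traj.frame_rate, traj.px_per_mm
    w = min(cfg.smoothing_window,
            traj.n_frames if traj.n_frames % 2 == 1 else traj.n_frames - 1)
    headomega = moving_average(
        differentiate_angle(headtheta_f, fs, cfg.angle_stencil), w)
    bodyomega = moving_average(
        differentiate_angle(bodytheta_f, fs, cfg.angle_stencil), w)
    tailspeed = moving_average(
        compute_speed(tail, fs, ppmm, cfg.speed_stencil), w)
    return KinematicSeries(
        headspeed=compute_speed(head, fs, ppmm, cfg.speed_stencil),
        midspeed=compute_speed(mid, fs, ppmm, cfg.speed_stencil),
        tailspeed=tailspeed,
        cmspeed=compute_speed(cm, fs, ppmm, cfg.speed_stencil),
        headtheta=headtheta_f,
        headomega=headomega,
        bodytheta=bodytheta_f,
        bodyomega=bodyomega,
        valid=~invalid,
    )
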