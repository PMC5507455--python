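"""Stop periods, headomega peaks, and head-cast events.

The behavioral grammar of a larval turn starts with a stop: tailspeed
drops below 0.21 mm/s. Within a stop the larva sweeps its head; each
supra-threshold |headomega| peak (> 0.35 rad/s) is a head cast. A cast
ends when headomega returns to zero after the peak. A cast with no
further cast in the same stop period is *accepted* (the larva commits
to the sampled direction); a cast followed by another is *rejected*.

Turning also straightens the body, which produces headomega peaks that
are not head casts; candidates over which |headtheta| net-decreases are
excluded as straightening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config, ConfigError
from .kinematics import KinematicSeries


@dataclass
class StopPeriod:
    """Maximal sub-threshold tailspeed interval (frames inclusive)."""

    start_frame: int
    end_frame: int
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("stop period start must not exceed end")

    def contains(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame


@dataclass
class HeadCast:
    """One detected head cast.

    ``peak_omega`` keeps the sign of the sweep (positive = counter-
    clockwise); ``amplitude`` is its magnitude, the head-cast size
    measure. ``accepted``/``success`` are filled by later stages.
    """

    stop_index: int
    ordinal: int               # 1-based within the stop period
    start_frame: int
    peak_frame: int
    end_frame: int
    peak_omega: float
    accepted: bool | None = None
    success: bool | None = None
    head_end: tuple[float, float] | None = None

    @property
    def amplitude(self) -> float:
        return abs(self.peak_omega)

    @property
    def direction(self) -> str:
        return "left" if self.peak_omega > 0 else "right"


def detect_stop_periods(tailspeed: np.ndarray, cfg: Config) -> list[StopPeriod]:
    """Maximal sub-threshold runs of (smoothed) tailspeed.

    Runs separated by above-threshold gaps no longer than
    ``cfg.max_stop_gap`` are merged (brief excursions belong to one
    continuous stop); merged runs shorter than ``cfg.min_stop_duration``
    are discarded. Returned sorted by start frame.
    """
    ts = np.asarray(tailspeed, dtype=float)
    if ts.size == 0:
        return []
    below = ts < cfg.tailspeed_stop_thresh
    # run-length encode sub-threshold stretches
    runs: list[list[int]] = []
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    max_gap = int(round(cfg.max_stop_gap * cfg.frame_rate))
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_frames = int(round(cfg.min_stop_duration * cfg.frame_rate))
    out = []
    for a, b in merged:
        if b - a + 1 >= min_frames:
            out.append(StopPeriod(a, b, duration=(b - a + 1) / cfg.frame_rate))
    return out


def peakdet(series: np.ndarray, delta: float) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Delta-commit local extremum detector.

    Scans the series keeping a running max and min. A maximum is
    committed at the running-max position once the series falls more
    than ``delta`` below that max; a minimum symmetrically once it
    rises more than ``delta`` above the running min. Committed maxima
    and minima strictly alternate in time. Strictly monotone series
    commit nothing.

    Returns ``(maxima, minima)`` as lists of ``(index, value)``.
    """
    if not delta > 0:
        raise ConfigError("peakdet delta must be > 0")
    x = np.asarray(series, dtype=float)
    maxima: list[tuple[int, float]] = []
    minima: list[tuple[int, float]] = []
    mx, mn = -np.inf, np.inf
    mxpos = mnpos = 0
    look_for_max = True
    for i, v in enumerate(x):
        if v > mx:
            mx, mxpos = v, i
        if v < mn:
            mn, mnpos = v, i
        if look_for_max:
            if v < mx - delta:
                maxima.append((mxpos, mx))
                mn, mnpos = v, i
                look_for_max = False
        else:
            if v > mn + delta:
                minima.append((mnpos, mn))
                mx, mxpos = v, i
                look_for_max = True
    return maxima, minima


def _cast_span(signed: np.ndarray, lo: int, hi: int, peak: int) -> tuple[int, int]:
    """Cast span around a peak of signed headomega.

    The cast runs from the nearest frame at or before the peak where
    headomega is zero or of opposite sign (else the stop start ``lo``)
    to the first such frame after the peak (else the stop end ``hi``) —
    "a head cast ended when headomega following the peak dropped to
    zero", operationalized as first exact zero or sign change because
    smoothed signals rarely hit 0 exactly.
    """
    positive = signed[peak] > 0
    start = lo
    for i in range(peak - 1, lo - 1, -1):
        if signed[i] == 0 or (signed[i] > 0) != positive:
            start = i
            break
    end = hi
    for i in range(peak + 1, hi + 1):
        if signed[i] == 0 or (signed[i] > 0) != positive:
            end = i
            break
    return start, end


def detect_head_casts(kin: KinematicSeries, stops: list[StopPeriod], cfg: Config) -> list[HeadCast]:
    """Head casts within each stop period.

    Candidate peaks come from :func:`peakdet` on |headomega| restricted
    to the stop; peaks at or below ``cfg.headomega_peak_thresh`` are
    dropped. Each cast spans from the preceding zero crossing of signed
    headomega (or the stop start) to the first zero crossing after the
    peak (or the stop end). Candidates whose span net-straightens the
    body (|headtheta| falls by more than ``cfg.straighten_drop``) are
    body-straightening artifacts, not casts, and are excluded.
    """
    omega = np.asarray(kin.headomega, dtype=float)
    theta = np.asarray(kin.headtheta, dtype=float)
    casts: list[HeadCast] = []
    for si, stop in enumerate(stops):
        lo, hi = stop.start_frame, min(stop.end_frame, len(omega) - 1)
        if hi <= lo:
            continue
        seg = np.abs(omega[lo:hi + 1])
        maxima, _ = peakdet(seg, cfg.peak_delta)
        ordinal = 0
        prev_end = lo
        for rel_pos, value in maxima:
            if value <= cfg.headomega_peak_thresh:
                continue
            peak = lo + rel_pos
            start, end = _cast_span(omega, max(lo, prev_end), hi, peak)
            if abs(theta[end]) < abs(theta[start]) - cfg.straighten_drop:
                continue  # net body straightening, not a cast
            ordinal += 1
            casts.append(HeadCast(stop_index=si, ordinal=ordinal,
                                  start_frame=start, peak_frame=peak, end_frame=end,
                                  peak_omega=float(omega[peak])))
            prev_end = end
    return casts


def label_acceptance(casts: list[HeadCast]) -> list[HeadCast]:
    """Set accepted/rejected flags for the casts of one stop period.

    Every cast followed by another cast in the same stop period is
    rejected; the last cast is accepted.
    """
    if not casts:
        return casts
    stop_set = {c.stop_index for c in casts}
    if len(stop_set) != 1:
        raise ValueError("label_acceptance expects casts from a single stop period")
    ordered = sorted(casts, key=lambda c: c.peak_frame)
    for c in ordered[:-1]:
        c.accepted = False
    ordered[-1].accepted = True
    return ordered


def segment_trajectory(kin: KinematicSeries, cfg: Config) -> tuple[list[StopPeriod], list[HeadCast]]:
    """Stops + acceptance-labeled casts for one kinematic series."""
    stops = detect_stop_periods(kin.tailspeed, cfg)
    casts = detect_head_casts(kin, stops, cfg)
    for si in range(len(stops)):
        label_acceptance([c for c in casts if c.stop_index == si])
    return stops, casts
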