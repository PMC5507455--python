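"""Turn events: assembly, light-relatedness, and avoidance scoring.

A complete turning event is a stop period, one or more head casts, and
finally a supra-threshold |bodyomega| peak marking the reorientation of
the midpoint-tail axis. Turns with exactly one cast before the body
turn are 1-cast turns; two or more make an n-cast turn.

Only turns plausibly driven by the light spot are analyzed: initiated
within 20 px outside or 50 px inside the nominal spot edge, and before
5 s of cumulative light exposure. A cast or turn succeeds when it
leaves the larval head outside the scatter-expanded (+10 px) spot edge
at its end; a trial escapes when any of its light-related turns
succeeds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .arena import LightSpot, cumulative_exposure, head_in_light, signed_distance
from .config import Config
from .kinematics import KinematicSeries, Trajectory
from .segmentation import HeadCast, StopPeriod, peakdet


class TurnKind(str, enum.Enum):
    ONE_CAST = "ONE_CAST"
    N_CAST = "N_CAST"


@dataclass
class TurnEvent:
    """One classified turning event."""

    stop_index: int
    casts: list[HeadCast]
    turn_peak_frame: int
    turn_peak_omega: float
    stop_start_frame: int = 0
    init_distance: float = float("nan")   # signed px, head to nominal edge at stop start
    light_related: bool | None = None
    success: bool | None = None

    @property
    def n_casts(self) -> int:
        return len(self.casts)

    @property
    def kind(self) -> TurnKind:
        return TurnKind.ONE_CAST if self.n_casts == 1 else TurnKind.N_CAST

    @property
    def init_inside(self) -> bool:
        return self.init_distance < 0

    @property
    def first_cast(self) -> HeadCast:
        return self.casts[0]


@dataclass
class TrialResult:
    """Per-trial classification outcome.

    ``escaped`` is defined only for trials with at least one
    light-related turn (None otherwise) and is true when any such turn
    ended with the head out of light.
    """

    trial_id: str
    turns: list[TurnEvent] = field(default_factory=list)
    stops: list[StopPeriod] = field(default_factory=list)
    casts: list[HeadCast] = field(default_factory=list)
    escaped: bool | None = None

    @property
    def light_related_turns(self) -> list[TurnEvent]:
        return [t for t in self.turns if t.light_related]


def assemble_turns(stops: list[StopPeriod], casts: list[HeadCast],
                   bodyomega: np.ndarray, cfg: Config) -> list[TurnEvent]:
    """Join stops, casts and the body-turn signal into turn events.

    For each stop period with at least one cast, the turn peak is the
    first |bodyomega| peak exceeding ``cfg.bodyomega_turn_thresh``
    after the first cast's peak and before the next stop period. The
    turn comprises the casts whose peaks precede the turn peak; casts
    later in the same stop period (after the body has already turned)
    belong to the stop but not to the turn. Stop periods whose casts
    have no qualifying body-turn peak emit nothing.
    """
    omega = np.asarray(bodyomega, dtype=float)
    turns: list[TurnEvent] = []
    for si, stop in enumerate(stops):
        stop_casts = sorted((c for c in casts if c.stop_index == si),
                            key=lambda c: c.peak_frame)
        if not stop_casts:
            continue
        window_start = stop_casts[0].peak_frame
        window_end = stops[si + 1].start_frame if si + 1 < len(stops) else len(omega)
        seg = np.abs(omega[window_start:window_end])
        maxima, _ = peakdet(seg, cfg.peak_delta)
        qualifying = [(window_start + pos, val) for pos, val in maxima
                      if val > cfg.bodyomega_turn_thresh]
        if not qualifying:
            continue
        peak_frame, _ = qualifying[0]
        turn_casts = [c for c in stop_casts if c.peak_frame <= peak_frame]
        if not turn_casts:
            continue
        turns.append(TurnEvent(stop_index=si, casts=turn_casts,
                               turn_peak_frame=peak_frame,
                               turn_peak_omega=float(omega[peak_frame]),
                               stop_start_frame=stop.start_frame))
    return turns


def is_light_related(turn: TurnEvent, exposure: np.ndarray, cfg: Config) -> bool:
    """Light-avoidance relatedness of a turn.

    True iff the turn was initiated within ``cfg.relate_out_px`` outside
    or ``cfg.relate_in_px`` inside the nominal spot edge, and cumulative
    light exposure at the stop start was below ``cfg.exposure_cutoff_s``.
    ``turn.init_distance`` must already be set.
    """
    d = turn.init_distance
    if not np.isfinite(d):
        return False
    if d >= 0:
        near = d <= cfg.relate_out_px
    else:
        near = -d <= cfg.relate_in_px
    return bool(near) and float(exposure[turn.stop_start_frame]) < cfg.exposure_cutoff_s


def score_cast_success(cast: HeadCast, traj: Trajectory, spot: LightSpot, cfg: Config) -> bool:
    """True iff the head is out of the expanded spot at the cast's end."""
    p = traj.head[cast.end_frame]
    return not bool(head_in_light(p, spot, cfg.success_margin_px))


def score_turn_success(turn: TurnEvent, traj: Trajectory, spot: LightSpot, cfg: Config) -> bool:
    """True iff the head is out of the expanded spot at the turn peak."""
    p = traj.head[min(turn.turn_peak_frame, traj.n_frames - 1)]
    return not bool(head_in_light(p, spot, cfg.success_margin_px))


def score_trial_escape(trial: TrialResult) -> bool | None:
    """Overall per-trial light-avoidance success.

    True iff any light-related turn succeeded; None (undefined, the
    trial enters no escape-rate denominator) when the trial has no
    light-related turn.
    """
    related = trial.light_related_turns
    if not related:
        return None
    return any(t.success for t in related)


def compute_heading_angle(traj: Trajectory, spot: LightSpot, at_frame: int) -> float:
    """Acute angle (degrees, 0-90) between larval heading and the spot edge.

    Heading is the mid->head direction at ``at_frame``; the edge
    direction is the tangent of the spot boundary at the boundary point
    nearest the head. 0 means skimming along the edge, 90 means heading
    straight into (or out of) the spot. NaN when undefined (head at the
    spot center, or degenerate mid/head).
    """
    head = traj.head[at_frame]
    mid = traj.mid[at_frame]
    heading = head - mid
    if not spot.is_circle:
        raise NotImplementedError("heading angle is defined for circular spots")
    radial = head - np.asarray(spot.center, dtype=float)
    if np.linalg.norm(radial) == 0 or np.linalg.norm(heading) == 0:
        return float("nan")
    tangent = np.array([-radial[1], radial[0]])
    tangent /= np.linalg.norm(tangent)
    heading = heading / np.linalg.norm(heading)
    cosang = abs(float(np.dot(heading, tangent)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def classify_trial(traj: Trajectory, kin: KinematicSeries,
                   stops: list[StopPeriod], casts: list[HeadCast],
                   spot: LightSpot, cfg: Config) -> TrialResult:
    """Full per-trial classification: turns, relatedness, success, escape."""
    exposure = cumulative_exposure(traj, spot, cfg.success_margin_px)
    for cast in casts:
        cast.success = score_cast_success(cast, traj, spot, cfg)
        cast.head_end = tuple(traj.head[cast.end_frame])
    turns = assemble_turns(stops, casts, kin.bodyomega, cfg)
    for turn in turns:
        turn.init_distance = float(
            signed_distance(traj.head[turn.stop_start_frame], spot))
        turn.light_related = is_light_related(turn, exposure, cfg)
        turn.success = score_turn_success(turn, traj, spot, cfg)
    trial = TrialResult(trial_id=traj.trial_id, turns=turns, stops=stops, casts=casts)
    trial.escaped = score_trial_escape(trial)
    return trial
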