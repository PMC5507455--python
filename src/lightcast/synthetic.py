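"""Scripted larval trajectories with ground-truth behavioral labels.

The generator emulates the tracking output of a light-spot phototaxis
assay: 60 fps head/midpoint/tail/centroid point tracks at 11.94 px/mm,
around a 2-cm circular light spot. A trial is a program of runs
(peristaltic forward motion with a small speed ripple), stop periods
(tail fixed), head casts (raised-cosine angular-velocity pulses
rotating the head-midpoint segment about the midpoint) and body turns
(pulses rotating the whole body about the tail), plus optional
Gaussian positional jitter.

The body is a rigid 3-point model: head-mid and mid-tail segments of
2 mm each (total ~4 mm, one larval length). Stops are posed with the
body axis radial toward the spot center and headtheta 0, so the head
radius reached by each cast has a closed form (law of cosines about
the midpoint) and every cast's end-inside/outside-light label is exact
by construction. Named fixtures (F46, F35, AMP, STRAIGHT) encode event
compositions whose summary statistics are known by rational
arithmetic, giving the pipeline a fully labeled acceptance surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arena import LightSpot
from .config import Config
from .kinematics import Trajectory


class GenerationError(ValueError):
    """Script is geometrically or behaviorally unsatisfiable."""


SEGMENT_MM = 2.0          # head-mid and mid-tail segment lengths
RUN_SPEED_MM_S = 1.5      # default crawl speed
RIPPLE_MM_S = 0.1         # peristaltic tailspeed ripple amplitude (< 0.5x stop thresh)
RIPPLE_HZ = 1.5
CAST_DURATION_S = 2.2     # default cast pulse length; long enough that the
                          # default smoothing chain keeps the peak within 5 %
STILL_PAD_FRAMES = 40     # still frames at stop start/end
GAP_FRAMES = 10           # still frames between pulses
RELAX_OMEGA = 0.25        # head straightening rate during runs, rad/s
STEER_OMEGA = 0.15        # run steering rate cap, rad/s (sub-threshold)


@dataclass(frozen=True)
class CastScript:
    """One scripted head cast.

    Either give ``target_offset_px`` (end head radius relative to the
    nominal spot edge; the rotation is solved from geometry) or an
    explicit ``peak_omega`` with ``duration_s`` (the reached radius is
    then implied). ``end_inside_light`` declares the intended label
    against the scatter-expanded edge and is verified at generation.
    """

    target_offset_px: float | None = None
    end_inside_light: bool | None = None
    peak_omega: float | None = None
    duration_s: float = CAST_DURATION_S
    side: str = "alternate"   # "alternate" | "same": sign policy vs previous cast


@dataclass(frozen=True)
class TurnScript:
    """One scripted turning event (a stop period and its contents)."""

    init_distance: float                      # signed px at stop start
    casts: tuple[CastScript, ...] = ()
    do_body_turn: bool = True
    body_turn_peak_omega: float | None = None  # auto if None
    body_turn_duration_s: float | None = None
    trailing_cast: bool = False               # extra cast after the body turn,
                                              # same stop period (rejects the
                                              # previous cast without joining the turn)
    straighten_pulse_peak: float | None = None  # body-straightening artifact scenario


@dataclass(frozen=True)
class TrialScript:
    turns: tuple[TurnScript, ...] = ()
    bearing: float = 0.0                      # placement angle around the spot
    approach_speed_mm_s: float = RUN_SPEED_MM_S
    run_only_s: float = 0.0                   # pure-run trial length if no turns
    hold_headtheta: float = 0.0               # bent-body approach (straightening scenario)


@dataclass(frozen=True)
class FixtureSpec:
    trials: tuple[TrialScript, ...]
    arena: LightSpot
    noise_sd: float = 0.0
    seed: int = 0
    frame_rate: float = 60.0
    px_per_mm: float = 11.94


# ---------------------------------------------------------------- ground truth

@dataclass
class TruthCast:
    stop_index: int
    ordinal: int
    peak_frame: int
    end_frame: int           # last pulse frame (headomega back at zero)
    amplitude: float
    success: bool
    accepted: bool
    in_turn: bool            # peak precedes the body-turn peak


@dataclass
class TruthTurn:
    stop_index: int
    n_casts: int
    success: bool
    peak_frame: int
    init_distance: float
    light_related: bool

    @property
    def kind(self) -> str:
        return "ONE_CAST" if self.n_casts == 1 else "N_CAST"


@dataclass
class TrialTruth:
    trial_id: str
    stops: list[tuple[int, int]] = field(default_factory=list)
    casts: list[TruthCast] = field(default_factory=list)
    turns: list[TruthTurn] = field(default_factory=list)
    escaped: bool | None = None


# ---------------------------------------------------------------- simulator

def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    return math.atan2(u[0] * v[1] - u[1] * v[0], float(np.dot(u, v)))


def _raised_cosine(total_angle: float, n: int) -> np.ndarray:
    """Angular-velocity samples integrating exactly to total_angle over n frames."""
    s = np.arange(n)
    w = 1.0 - np.cos(2.0 * math.pi * s / n)
    return total_angle * w / w.sum()


class _Body:
    """Rigid 3-point larva; records one pose per frame."""

    def __init__(self, tail: np.ndarray, beta: float, h: float,
                 seg_px: float, dt: float):
        self.tail = np.asarray(tail, dtype=float)
        self.beta = float(beta)
        self.h = float(h)
        self.L = seg_px
        self.dt = dt
        self.frames: list[tuple[float, float, float, float]] = []  # tail_x, tail_y, beta, h

    @property
    def mid(self) -> np.ndarray:
        return self.tail + self.L * _unit(self.beta)

    @property
    def head(self) -> np.ndarray:
        return self.mid + self.L * _unit(self.beta + self.h)

    def record(self) -> None:
        self.frames.append((self.tail[0], self.tail[1], self.beta, self.h))

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _solve_alpha(r_m: float, L: float, r_target: float, trial_id: str) -> float:
    """Head-axis angle off the mid->center line reaching radius r_target."""
    arg = (r_m * r_m + L * L - r_target * r_target) / (2.0 * r_m * L)
    if not -1.0 <= arg <= 1.0:
        raise GenerationError(
            f"{trial_id}: cast cannot reach head radius {r_target:.1f} px "
            f"from mid radius {r_m:.1f} px with a {L:.1f} px head segment")
    return math.acos(arg)


def simulate_trial(script: TrialScript, arena: LightSpot, cfg: Config,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None,
                   trial_id: str = "trial") -> tuple[Trajectory, TrialTruth]:
    """Generate one trial trajectory and its ground-truth labels.

    Raises :class:`GenerationError` when a scripted event is
    geometrically unsatisfiable (unreachable cast target, sub-threshold
    pulse, or a light-related turn that would start after the exposure
    cutoff).
    """
    if not arena.is_circle:
        raise GenerationError("the simulator scripts circular light spots")
    rng = rng or np.random.default_rng(0)
    dt = 1.0 / cfg.frame_rate
    L = SEGMENT_MM * cfg.px_per_mm
    R = arena.radius
    center = np.asarray(arena.center, dtype=float)
    margin = cfg.success_margin_px
    truth = TrialTruth(trial_id=trial_id)

    e_out = _unit(script.bearing)
    v_px = script.approach_speed_mm_s * cfg.px_per_mm

    if not script.turns:
        n = max(2, int(round((script.run_only_s or 3.0) * cfg.frame_rate)))
        start_r = R + 90.0
        body = _Body(center + (start_r + 2 * L) * e_out, script.bearing + math.pi,
                     script.hold_headtheta, L, dt)
        for i in range(n):
            body.record()
            speed = v_px + RIPPLE_MM_S * cfg.px_per_mm * math.sin(2 * math.pi * RIPPLE_HZ * i * dt)
            body.tail = body.tail + speed * dt * _unit(body.beta)
        return _finish(body, truth, arena, cfg, noise_sd, rng, trial_id)

    d0 = script.turns[0].init_distance
    approach_px = max(25.0, v_px * 1.2)
    start_r = max(R + d0, R + margin + 5.0) + approach_px
    body = _Body(center + (start_r + 2 * L) * e_out, script.bearing + math.pi,
                 script.hold_headtheta, L, dt)

    exposure = 0.0  # cumulative seconds head-in-expanded-spot, noise-free

    def head_radius() -> float:
        return float(np.linalg.norm(body.head - center))

    def step_exposure() -> None:
        nonlocal exposure
        if head_radius() < R + margin:
            exposure += dt

    def run_until(target_r: float, min_s: float = 0.5, pursue: bool = True) -> None:
        """Crawl forward (with ripple) until the head radius drops to target_r."""
        if head_radius() <= target_r:
            raise GenerationError(
                f"{trial_id}: head already inside the next scripted start radius")
        i = 0
        while head_radius() > target_r or i < min_s * cfg.frame_rate:
            body.record()
            step_exposure()
            if pursue:
                desired = math.atan2(*(center - body.head)[::-1])
                err = _signed_angle(_unit(body.beta), _unit(desired))
                body.beta += float(np.clip(err, -STEER_OMEGA * dt, STEER_OMEGA * dt))
            if body.h != 0.0 and script.hold_headtheta == 0.0:
                drop = min(abs(body.h), RELAX_OMEGA * dt)
                body.h -= math.copysign(drop, body.h)
            speed = v_px + RIPPLE_MM_S * cfg.px_per_mm * math.sin(
                2 * math.pi * RIPPLE_HZ * i * dt)
            body.tail = body.tail + speed * dt * _unit(body.beta)
            i += 1
            if i > 120 * cfg.frame_rate:
                raise GenerationError(f"{trial_id}: run never reached its target radius")

    def still(n: int) -> None:
        for _ in range(n):
            body.record()
            step_exposure()

    def pulse_head(delta: float, n: int) -> int:
        """Rotate headtheta by delta over n frames; return the peak frame."""
        omega = _raised_cosine(delta, n)
        peak_frame = body.n_frames + int(np.argmax(np.abs(omega)))
        for w in omega:
            body.record()
            step_exposure()
            body.h += float(w)
        return peak_frame

    def pulse_body(delta: float, n: int) -> int:
        omega = _raised_cosine(delta, n)
        peak_frame = body.n_frames + int(np.argmax(np.abs(omega)))
        for w in omega:
            body.record()
            step_exposure()
            body.beta += float(w)
        return peak_frame

    for ti, turn in enumerate(script.turns):
        if ti > 0:
            run_until(R + turn.init_distance)
        else:
            run_until(R + turn.init_distance, min_s=1.0, pursue=False)

        stop_start = body.n_frames
        init_distance = head_radius() - R
        exposure_at_start = exposure
        if exposure_at_start >= cfg.exposure_cutoff_s - 0.5:
            raise GenerationError(
                f"{trial_id}: turn {ti} would start at {exposure_at_start:.2f} s "
                "of light exposure, too close to the relatedness cutoff")
        still(STILL_PAD_FRAMES)

        cast_truths: list[TruthCast] = []
        for ci, cast in enumerate(turn.casts):
            mid = body.mid
            r_m = float(np.linalg.norm(mid - center))
            e_c = (center - mid) / r_m
            alpha_cur = _signed_angle(e_c, _unit(body.beta + body.h))
            if cast.side == "same" and ci > 0:
                sign = math.copysign(1.0, alpha_cur) if alpha_cur else 1.0
            elif ci == 0:
                sign = 1.0 if alpha_cur >= 0 else -1.0
            else:
                sign = -math.copysign(1.0, alpha_cur) if alpha_cur else 1.0
            if cast.peak_omega is not None:
                n = max(4, int(round(cast.duration_s * cfg.frame_rate)))
                n += n % 2
                delta = sign * cast.peak_omega * n * dt / 2.0
            else:
                alpha_t = _solve_alpha(r_m, L, R + cast.target_offset_px, trial_id)
                delta = sign * alpha_t - alpha_cur
            if abs(body.h + delta) < abs(body.h) - 0.02:
                raise GenerationError(
                    f"{trial_id}: cast {ci + 1} of turn {ti} would net-straighten "
                    "the body and be excluded by the detector")
            if cast.peak_omega is None:
                n = max(4, int(round(cast.duration_s * cfg.frame_rate)))
                n += n % 2
                # small rotations at the default duration would be too slow to
                # detect; shorten the pulse toward a ~1.2 rad/s peak instead
                if abs(2.0 * delta / (n * dt)) <= 2.2 * cfg.headomega_peak_thresh:
                    n = max(24, int(round(2.0 * abs(delta) * cfg.frame_rate / 1.2)))
                    n += n % 2
            peak_value = abs(2.0 * delta / (n * dt))
            if peak_value <= 2.0 * cfg.headomega_peak_thresh:
                raise GenerationError(
                    f"{trial_id}: cast {ci + 1} of turn {ti} peaks at "
                    f"{peak_value:.2f} rad/s, below 2x the detection threshold")
            pk = pulse_head(delta, n)
            pulse_end = body.n_frames - 1
            still(GAP_FRAMES)
            success = head_radius() >= R + margin
            if cast.end_inside_light is not None and success == cast.end_inside_light:
                raise GenerationError(
                    f"{trial_id}: cast {ci + 1} of turn {ti} ended at head radius "
                    f"{head_radius():.1f} px, contradicting its scripted label")
            cast_truths.append(TruthCast(
                stop_index=ti, ordinal=ci + 1, peak_frame=pk, end_frame=pulse_end,
                amplitude=peak_value, success=success, accepted=False, in_turn=True))

        if turn.straighten_pulse_peak is not None:
            mag = abs(body.h)
            if mag < 0.2:
                raise GenerationError(f"{trial_id}: straightening scenario needs a bent body")
            n = max(4, int(round(2.0 * mag / turn.straighten_pulse_peak * cfg.frame_rate)))
            n += n % 2
            pulse_head(-body.h, n)
            still(GAP_FRAMES)

        turn_success = None
        turn_peak = None
        if turn.do_body_turn:
            if not turn.casts and turn.straighten_pulse_peak is None:
                raise GenerationError(f"{trial_id}: a body turn needs at least one cast")
            head_out = head_radius() >= R + margin
            psi = _signed_angle((center - body.tail) / np.linalg.norm(center - body.tail),
                                (body.head - body.tail) / np.linalg.norm(body.head - body.tail))
            away = math.copysign(1.0, psi) if psi else 1.0
            if head_out:
                peak = turn.body_turn_peak_omega or 1.0
                dur = turn.body_turn_duration_s or 0.6
                sign = away
            else:
                peak = turn.body_turn_peak_omega or 0.8
                dur = turn.body_turn_duration_s or 0.6
                sign = -away
            n = int(round(dur * cfg.frame_rate))
            n += n % 2
            turn_peak = pulse_body(sign * peak * n * dt / 2.0, n)
            still(GAP_FRAMES)
            turn_success = head_radius() >= R + margin
            if turn_success != head_out:
                raise GenerationError(
                    f"{trial_id}: body turn of turn {ti} moved the head across "
                    "the expanded spot edge; adjust the scripted rotation")

        if turn.trailing_cast:
            if not cast_truths:
                raise GenerationError(f"{trial_id}: trailing cast needs a preceding cast")
            mag = 2.0 * abs(body.h)
            n = max(4, int(round(CAST_DURATION_S * cfg.frame_rate)))
            n += n % 2
            pk = pulse_head(-math.copysign(mag, body.h), n)
            pulse_end = body.n_frames - 1
            still(GAP_FRAMES)
            cast_truths.append(TruthCast(
                stop_index=ti, ordinal=len(cast_truths) + 1, peak_frame=pk,
                end_frame=pulse_end, amplitude=2.0 * mag / (n * dt),
                success=head_radius() >= R + margin, accepted=False, in_turn=False))

        still(STILL_PAD_FRAMES)
        stop_end = body.n_frames - 1
        truth.stops.append((stop_start, stop_end))

        if cast_truths:
            cast_truths[-1].accepted = True
        truth.casts.extend(cast_truths)
        if turn_peak is not None and cast_truths:
            in_turn = [c for c in cast_truths if c.peak_frame <= turn_peak]
            for c in cast_truths:
                c.in_turn = c.peak_frame <= turn_peak
            d = init_distance
            related = ((d >= 0 and d <= cfg.relate_out_px)
                       or (d < 0 and -d <= cfg.relate_in_px)) \
                and exposure_at_start < cfg.exposure_cutoff_s
            truth.turns.append(TruthTurn(
                stop_index=ti, n_casts=len(in_turn), success=bool(turn_success),
                peak_frame=turn_peak, init_distance=init_distance,
                light_related=bool(related)))

        if ti < len(script.turns) - 1:
            continue  # the next run_until supplies the inter-stop crawl
        # crawl off along the (possibly reoriented) body axis
        exit_frames = int(round(1.2 * cfg.frame_rate))
        for i in range(exit_frames):
            body.record()
            step_exposure()
            if body.h != 0.0:
                drop = min(abs(body.h), RELAX_OMEGA * dt)
                body.h -= math.copysign(drop, body.h)
            speed = v_px + RIPPLE_MM_S * cfg.px_per_mm * math.sin(
                2 * math.pi * RIPPLE_HZ * i * dt)
            body.tail = body.tail + speed * dt * _unit(body.beta)

    related_success = [t for t in truth.turns if t.light_related]
    truth.escaped = (any(t.success for t in related_success)
                     if related_success else None)
    return _finish(body, truth, arena, cfg, noise_sd, rng, trial_id)


def _finish(body: _Body, truth: TrialTruth, arena: LightSpot, cfg: Config,
            noise_sd: float, rng: np.random.Generator,
            trial_id: str) -> tuple[Trajectory, TrialTruth]:
    arr = np.asarray(body.frames, dtype=float)
    tail = arr[:, 0:2]
    beta = arr[:, 2]
    h = arr[:, 3]
    L = body.L
    mid = tail + L * np.column_stack([np.cos(beta), np.sin(beta)])
    head = mid + L * np.column_stack([np.cos(beta + h), np.sin(beta + h)])
    centroid = (tail + mid + head) / 3.0
    if noise_sd > 0:
        tail = tail + rng.normal(0.0, noise_sd, tail.shape)
        mid = mid + rng.normal(0.0, noise_sd, mid.shape)
        head = head + rng.normal(0.0, noise_sd, head.shape)
        centroid = centroid + rng.normal(0.0, noise_sd, centroid.shape)
    traj = Trajectory(frame_index=np.arange(len(tail)), head=head, mid=mid,
                      tail=tail, centroid=centroid, frame_rate=cfg.frame_rate,
                      px_per_mm=cfg.px_per_mm, trial_id=trial_id)
    return traj, truth


# ---------------------------------------------------------------- fixtures

def _cast(offset: float, inside: bool) -> CastScript:
    return CastScript(target_offset_px=offset, end_inside_light=inside)


def _f46_turnscripts() -> list[TurnScript]:
    """46 light-related turns reproducing the assay's headline rate statistics.

    28 one-cast turns (14 successful), 11 two-cast and 7 three-cast
    turns (9 n-cast successes, 2 successful first casts). Two one-cast
    turns carry a trailing post-turn cast in the same stop period,
    which rejects their first cast without changing the turn's cast
    count — yielding the 13/17 accepted/rejected split of failed first
    casts and the 13/16 acceptance of successful first casts.
    """
    succ_1 = TurnScript(init_distance=8.0, casts=(_cast(22.0, False),))
    fail_1 = TurnScript(init_distance=-15.0, casts=(_cast(-4.0, True),))
    two_fs = TurnScript(init_distance=-15.0,
                        casts=(_cast(-4.0, True), _cast(22.0, False)))
    two_ss = TurnScript(init_distance=-15.0,
                        casts=(_cast(22.0, False), _cast(24.0, False)))
    two_ff = TurnScript(init_distance=-15.0,
                        casts=(_cast(-4.0, True), _cast(2.0, True)))
    three_ffs = TurnScript(init_distance=-15.0,
                           casts=(_cast(-6.0, True), _cast(-1.0, True), _cast(22.0, False)))
    three_fff = TurnScript(init_distance=-15.0,
                           casts=(_cast(-6.0, True), _cast(-1.0, True), _cast(4.0, True)))
    scripts = (
        [succ_1] * 13 + [replace(succ_1, trailing_cast=True)]
        + [fail_1] * 13 + [replace(fail_1, trailing_cast=True)]
        + [two_fs] * 5 + [two_ss] * 2 + [two_ff] * 4
        + [three_ffs] * 2 + [three_fff] * 5
    )
    assert len(scripts) == 46
    return scripts


def _f35_turnscripts() -> list[TurnScript]:
    """35 single-turn trials, 25 of which escape (71.43 %)."""
    succ_1 = TurnScript(init_distance=8.0, casts=(_cast(22.0, False),))
    succ_2 = TurnScript(init_distance=-15.0,
                        casts=(_cast(-4.0, True), _cast(22.0, False)))
    fail_1 = TurnScript(init_distance=-15.0, casts=(_cast(-4.0, True),))
    fail_3 = TurnScript(init_distance=-15.0,
                        casts=(_cast(-6.0, True), _cast(-1.0, True), _cast(4.0, True)))
    return [succ_1] * 15 + [succ_2] * 10 + [fail_1] * 6 + [fail_3] * 4


def _amp_turnscripts() -> list[TurnScript]:
    """Two-cast turns with second-cast amplitudes scripted 1.5x the first."""
    out = []
    for a1 in np.linspace(1.2, 1.9, 8):
        out.append(TurnScript(init_distance=-15.0, casts=(
            CastScript(peak_omega=float(a1), duration_s=1.2),
            CastScript(peak_omega=float(1.5 * a1), duration_s=1.2, side="same"),
        )))
    return out


FIXTURE_NAMES = ("F46", "F35", "AMP", "STRAIGHT")


def make_fixture(name: str, seed: int = 0, noise_sd: float = 0.0,
                 cfg: Config | None = None) -> FixtureSpec:
    """Build a named fixture specification.

    F46 — 46 light-related turns with the reference composition;
    F35 — 35 single-turn trials, 25 escaping;
    AMP — amplitude-contrast fixture (second casts 1.5x first);
    STRAIGHT — body-straightening artifact scenario (no casts expected).
    """
    cfg = cfg or Config()
    arena = LightSpot.nominal(px_per_mm=cfg.px_per_mm)
    if name == "F46":
        turnscripts = _f46_turnscripts()
    elif name == "F35":
        turnscripts = _f35_turnscripts()
    elif name == "AMP":
        turnscripts = _amp_turnscripts()
    elif name == "STRAIGHT":
        straight = TrialScript(
            turns=(TurnScript(init_distance=-15.0, casts=(), do_body_turn=False,
                              straighten_pulse_peak=0.6),),
            hold_headtheta=1.0)
        return FixtureSpec(trials=(straight,), arena=arena, noise_sd=noise_sd, seed=seed,
                           frame_rate=cfg.frame_rate, px_per_mm=cfg.px_per_mm)
    else:
        raise GenerationError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    n = len(turnscripts)
    trials = tuple(
        TrialScript(turns=(ts,), bearing=2.0 * math.pi * i / n)
        for i, ts in enumerate(turnscripts))
    return FixtureSpec(trials=trials, arena=arena, noise_sd=noise_sd, seed=seed,
                       frame_rate=cfg.frame_rate, px_per_mm=cfg.px_per_mm)


def simulate_fixture(spec: FixtureSpec, cfg: Config | None = None
                     ) -> list[tuple[Trajectory, TrialTruth]]:
    """Simulate every trial of a fixture; deterministic in spec.seed."""
    cfg = cfg or Config(frame_rate=spec.frame_rate, px_per_mm=spec.px_per_mm)
    rng = np.random.default_rng(spec.seed)
    out = []
    for i, trial in enumerate(spec.trials):
        traj, truth = simulate_trial(trial, spec.arena, cfg, spec.noise_sd,
                                     rng, trial_id=f"trial_{i:03d}")
        out.append((traj, truth))
    return out
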