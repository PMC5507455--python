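# Methods

## Behavioral model

The analysis operates on a three-point reduction of the larva — head H,
midpoint M, tail T — tracked per video frame, plus the centroid. Two angles
carry the behavior:

* `headtheta` — the signed angle from the T→M direction to the M→H
  direction (0 for a straight body, positive counter-clockwise in a y-up
  arena frame). Its angular speed `headomega` is the head-cast indicator:
  casting sweeps the head about the midpoint, producing a single-signed
  pulse in headomega.
* `bodytheta` — the orientation of the T→M axis against the arena
  horizontal; its angular speed `bodyomega` marks body reorientation
  (turning).

A turning event is the sequence: tail speed drops below threshold (stop
onset) → one or more supra-threshold headomega peaks (casts) → a
supra-threshold bodyomega peak (the turn). Casts that are followed by
another cast in the same stop period are *rejected*, the last one is
*accepted*. Body straightening after a turn also bends headtheta back
toward zero and can produce headomega peaks that are not casts; candidate
casts over whose span |headtheta| net-decreases are therefore excluded.

Light-avoidance is scored against a circular light spot of 2 cm diameter
(radius 10 mm x 11.94 px/mm = 119.4 px). Distances from the head to the
nearest edge point are signed (positive outside). Because larvae sense
scattered light slightly beyond the nominal edge, success — head out of
light at the end of a cast (headomega back at zero) or of a turn (the
bodyomega peak) — is judged against the edge expanded outward 10 px. Turns
count as light-related only when initiated within 20 px outside or 50 px
inside the nominal edge and before 5 s of cumulative head-in-light time.
A trial escapes when any of its light-related turns succeeds; trials
without light-related turns enter no escape denominator.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| frame_rate | 60 | Hz | video frame rate |
| px_per_mm | 11.94 | px/mm | spatial calibration |
| tailspeed_stop_thresh | 0.21 | mm/s | stop-period definition (2.5 px/s) |
| headomega_peak_thresh | 0.35 | rad/s | head-cast detection (20.05 deg/s) |
| bodyomega_turn_thresh | 0.35 | rad/s | body-turn detection |
| min_stop_duration | 0.25 | s | discard shorter sub-threshold runs |
| max_stop_gap | 0.15 | s | merge stops split by brief excursions |
| peak_delta | 0.25 | rad/s | commit delta of the peak detector |
| smoothing_window | 9 | frames | moving average on headomega/bodyomega/tailspeed |
| position_smoothing_window | 9 | frames | moving average on raw coordinates |
| speed_stencil / angle_stencil | 10 / 8 | frames | central-difference half-widths |
| straighten_drop | 0.05 | rad | net `headtheta` drop that flags straightening |
| success_margin_px | 10 | px | scatter expansion of the spot edge |
| relate_out_px / relate_in_px | 20 / 50 | px | light-relatedness windows |
| exposure_cutoff_s | 5 | s | light-adaptation guard |

The behavioral thresholds (0.21 mm/s, 0.35 rad/s, 20/50/10 px, 5 s) are the
assay's standard definitions. The stop-duration, gap, and peak-delta values
are operational choices at sub-peristaltic-cycle scale for 60 fps recordings;
all are configurable through the JSON config.

## Numerical choices

**Differentiation and smoothing.** Tracked coordinates are smoothed with a
centered moving average (window 9, shrinking symmetrically at the edges)
before any derivative; speeds and angular speeds are symmetric central
differences `(x[i+k] - x[i-k]) / (2k dt)` with `k` = 10 frames for speeds
and 8 for angles, falling back to narrower symmetric stencils and one-sided
differences at the ends so every series keeps the trajectory's length.
headomega, bodyomega and tailspeed are additionally smoothed with the
9-frame moving average — these are the three signals the thresholds apply
to. The wide stencils are deliberate: point-tracking jitter of sd 0.5 px at
60 fps turns adjacent-frame differences into ~2 mm/s of rectified speed
noise, an order of magnitude above the 0.21 mm/s stop threshold; averaging
displacement over ±10 frames brings the noise floor to ~0.15 mm/s while a
constant crawl speed and linear angle ramps remain exact. The angular chain
attenuates a raised-cosine cast pulse of 2.2 s by under 5 % (shorter pulses
attenuate more; the detection threshold retains a >=2x margin down to
~0.5 s pulses).

**Peak detection.** The delta-commit scanner: a running maximum is committed
as a peak once the series falls more than `peak_delta` below it, then the
roles of maximum and minimum swap, so committed extrema strictly alternate.
Casts are detected on |headomega| so left and right sweeps are symmetric;
the sign at the peak recovers direction. `peak_delta` = 0.25 rad/s sits
below the 0.35 rad/s event threshold (no qualifying pulse is missed — every
pulse returns to zero) but above the residual noise ripple of the smoothed
signal, so one physical sweep commits exactly one peak.

**Cast span.** "headomega drops to zero" is operationalized as the first
exact zero or sign change after the peak (smoothed signals rarely hit zero
exactly); if none occurs before the stop end, the cast ends there. The span
start is the symmetric crossing before the peak, bounded by the previous
cast's end.

**Turn assembly.** The turn peak is the first qualifying |bodyomega| peak
after the *first* cast's peak and before the next stop period; the turn's
casts are those whose peaks precede it. Casts later in the same stop period
still reject their predecessors (acceptance is a stop-period property) but
do not change the turn's cast count — the anatomy that separates a 1-cast
turn from its post-turn head movements.

**Boundary conventions.** A point exactly on the (expanded) edge counts as
out of light, frame indices are 0-based, event intervals are inclusive, and
light exposure accumulates against the same 10-px-expanded region used for
success so "in light" has a single meaning throughout. Angles are radians
internally; degrees appear only in the heading-angle output.

**Degenerate input.** Frames with coincident body points yield flagged
invalid angles; gaps of at most 3 frames are linearly interpolated before
smoothing, longer gaps split the trajectory (`split_on_invalid`), and each
segment is analyzed independently.

**Statistics.** `fisher_exact` is the two-sided minimum-likelihood
convention (sum of all margin-preserving tables no more probable than the
observed one); tables with a zero margin are rejected as undefined.
`students_t` is the classic pooled-variance form with n1+n2-2 degrees of
freedom. Every reported rate is stored as numerator/denominator, so
percentages are exact ratios; empty denominators report as undefined, not
zero. No multiple-testing correction is applied.

## The simulator

`lightcast.synthetic` scripts trajectories rather than modeling larval
physiology. The body is rigid: two 2-mm segments (head-mid, mid-tail; total
~4 mm, one larval length). Runs advance the tail along the body axis at
1.5 mm/s with a ±0.1 mm/s peristaltic ripple — always clearly above the
stop threshold. Stops freeze the tail exactly. A cast rotates the
head-midpoint segment about the midpoint with a raised-cosine
angular-velocity pulse whose integral is solved in closed form (law of
cosines about the midpoint) so the head lands at a scripted radius relative
to the spot edge; the scripted inside/outside label is verified against the
generated geometry and a contradiction aborts generation. Body turns rotate
the whole body about the fixed tail, away from the spot when the turn is
meant to succeed and gently toward it otherwise. Stops are posed with the
body axis radial to the spot center, cast targets escalate in radius on
alternating sides (keeping |headtheta| non-decreasing, clear of the
straightening exclusion), and the default cast pulse lasts 2.2 s so the
analysis chain recovers scripted peak amplitudes within 5 % on noise-free
data. Optional Gaussian jitter (iid per point and frame) emulates tracking
noise; everything is deterministic given the seed.

Named fixtures encode event compositions by exact arithmetic:

* **F46** — 46 light-related turns: 28 one-cast (14 successful), 11
  two-cast, 7 three-cast, with 2 successful first casts inside n-cast turns.
  Two one-cast turns carry a trailing post-turn cast in the same stop
  period, making the accepted/rejected split of failed first casts 13/17
  and the acceptance of successful first casts 13/16. This is the only
  composition consistent with the full set of reference rates, whose raw
  cast counts are not mutually consistent under a casts-equal-turn-casts
  reading; the trailing-cast anatomy reconciles them.
* **F35** — 35 single-turn trials, 25 of which escape (71.43 %). The
  escape rate cannot be carried by the F46 composition itself (it contains
  only 23 successful turns), so F35 scripts its own per-trial outcomes.
* **AMP** — two-cast turns whose second-cast amplitudes are scripted 1.5x
  the first, for the amplitude-contrast t-test.
* **STRAIGHT** — a bent-body approach whose stop contains only a
  straightening pulse (peak 0.6 rad/s, above threshold) that the exclusion
  rule must reject.

What the simulator does *not* emulate: real peristaltic body deformation
(segments are rigid), closed-loop light-driven decisions (behavior is
scripted, not a policy), contour/skeleton extraction upstream of point
tracks, and the measured light-intensity profile. Passing tests therefore
demonstrate that the event definitions, thresholds, geometry and statistics
are implemented correctly and robustly to positional jitter — not that the
pipeline segments arbitrary real larval tracks perfectly.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the 46-
and 35-trial fixtures (~400-700 frames per trial), a 200-scenario cast-count
sweep, and a 20-seed jitter-robustness study (sd 0.5 px) — a few hundred
thousand frames in total, seconds of compute.

## Known limitations

* The straightening exclusion compares |headtheta| at the candidate span's
  ends; a genuine cast that ends much closer to the body axis than it
  started (a large un-bending sweep) would be excluded too. Scripted
  fixtures avoid that regime; real data near this boundary would need the
  threshold (`straighten_drop`) tuned.
* Cast end frames inherit the smoothing chain's half-reach (~0.2 s) of
  delay relative to the physical return-to-zero; success labels are robust
  to this because the head is stationary between events, but end-frame
  timestamps should not be read as precise to a frame (peak frames are).
* The heading-angle operation is defined for circular spots only.
* Polygonal spots are supported for geometry queries (signed distance,
  expansion via Minkowski buffer) but the simulator scripts circles only.
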