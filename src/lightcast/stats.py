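"""Summary statistics and significance tests for classified turns.

The report answers the questions the assay was designed for: how often
does a larva turn with one head cast versus several, how often does
each kind of turn (and each cast within a turn) get the head out of
the light, and are casts that fail accepted or followed by another?
Rates are stored as numerator/denominator pairs so every percentage is
exactly 100*num/den; group comparisons use the two-sided Fisher exact
test for rates and the pooled-variance Student t-test for head-cast
amplitudes (peak |headomega|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
from scipy import stats as sps

from .classification import TrialResult, TurnEvent, TurnKind


class StatsError(ValueError):
    """Undefined statistic (empty denominator or zero margin)."""


class Table2x2(NamedTuple):
    """2x2 count table, rows = groups, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        if min(self) < 0:
            raise StatsError("cell counts must be nonnegative")
        if (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0):
            raise StatsError("Fisher's exact test needs positive margins")


def fisher_exact(table: Table2x2) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood method).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (within a small tolerance) — the convention of mainstream
    statistics packages.
    """
    t = Table2x2(*table)
    t.validate()
    _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


def students_t(x, y) -> tuple[float, float]:
    """Classic pooled-variance Student t-test, two-sided.

    Returns ``(t, p)`` with n1+n2-2 degrees of freedom. Degenerate
    zero-variance samples give p=1 for equal means and p=0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (float("inf"), 0.0)
    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


@dataclass(frozen=True)
class Rate:
    """A count-based rate; percent is exactly 100*num/den."""

    num: int
    den: int

    @property
    def percent(self) -> float | None:
        if self.den == 0:
            return None
        return 100.0 * self.num / self.den

    def to_dict(self) -> dict[str, Any]:
        return {"num": self.num, "den": self.den, "percent": self.percent}


@dataclass
class SummaryReport:
    """All summary statistics of one analysis run."""

    # turn composition
    turns_1cast: Rate = Rate(0, 0)
    turns_2cast: Rate = Rate(0, 0)
    turns_3plus_cast: Rate = Rate(0, 0)
    # turn-level success
    success_1cast: Rate = Rate(0, 0)
    success_ncast: Rate = Rate(0, 0)
    escape_overall: Rate = Rate(0, 0)
    # first-cast statistics
    first_cast_success_1cast: Rate = Rate(0, 0)
    first_cast_success_ncast: Rate = Rate(0, 0)
    first_cast_success_pooled: Rate = Rate(0, 0)
    failed_first_rejected: Rate = Rate(0, 0)
    failed_second_rejected: Rate = Rate(0, 0)
    successful_first_accepted: Rate = Rate(0, 0)
    successful_second_accepted: Rate = Rate(0, 0)
    # per-ordinal success within n-cast turns
    ncast_success_by_ordinal: dict[str, Rate] = field(default_factory=dict)
    # amplitude samples (rad/s)
    amplitude_by_ordinal: dict[str, list[float]] = field(default_factory=dict)
    amplitude_failed_first_accepted: list[float] = field(default_factory=list)
    amplitude_failed_first_rejected: list[float] = field(default_factory=list)
    amplitude_failed_second_accepted: list[float] = field(default_factory=list)
    amplitude_failed_second_rejected: list[float] = field(default_factory=list)
    # heading-angle (deg) / first- and second-cast amplitude pairs
    heading_amplitude_first: list[tuple[float, float]] = field(default_factory=list)
    heading_amplitude_second: list[tuple[float, float]] = field(default_factory=list)
    # significance tests
    tests: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in ("turns_1cast", "turns_2cast", "turns_3plus_cast",
                     "success_1cast", "success_ncast", "escape_overall",
                     "first_cast_success_1cast", "first_cast_success_ncast",
                     "first_cast_success_pooled", "failed_first_rejected",
                     "failed_second_rejected", "successful_first_accepted",
                     "successful_second_accepted"):
            out[name] = getattr(self, name).to_dict()
        out["ncast_success_by_ordinal"] = {
            k: v.to_dict() for k, v in self.ncast_success_by_ordinal.items()}
        out["amplitude_by_ordinal"] = self.amplitude_by_ordinal
        out["amplitude_failed_first_accepted"] = self.amplitude_failed_first_accepted
        out["amplitude_failed_first_rejected"] = self.amplitude_failed_first_rejected
        out["amplitude_failed_second_accepted"] = self.amplitude_failed_second_accepted
        out["amplitude_failed_second_rejected"] = self.amplitude_failed_second_rejected
        out["heading_amplitude_first"] = self.heading_amplitude_first
        out["heading_amplitude_second"] = self.heading_amplitude_second
        out["tests"] = self.tests
        return out


def _ordinal_bin(k: int, top: int) -> str:
    return f"{k}" if k < top else f"{top}+"


def summarize(turns: list[TurnEvent], trials: list[TrialResult] | None = None,
              heading_pairs: tuple[list, list] | None = None) -> SummaryReport:
    """Build the summary report from light-related, scored turns.

    ``turns`` should already be restricted to light-related events;
    ``trials`` supplies the per-trial escape denominator (trials with
    at least one light-related turn). First-cast statistics pool the
    first cast of every turn regardless of kind; acceptance labels are
    stop-period properties, so a cast can be rejected by a later cast
    that is not part of the turn itself.
    """
    rep = SummaryReport()
    n = len(turns)
    one = [t for t in turns if t.kind is TurnKind.ONE_CAST]
    multi = [t for t in turns if t.kind is TurnKind.N_CAST]
    rep.turns_1cast = Rate(len(one), n)
    rep.turns_2cast = Rate(sum(1 for t in multi if t.n_casts == 2), n)
    rep.turns_3plus_cast = Rate(sum(1 for t in multi if t.n_casts >= 3), n)

    rep.success_1cast = Rate(sum(1 for t in one if t.success), len(one))
    rep.success_ncast = Rate(sum(1 for t in multi if t.success), len(multi))
    if trials is not None:
        scored = [tr for tr in trials if tr.escaped is not None]
        rep.escape_overall = Rate(sum(1 for tr in scored if tr.escaped), len(scored))

    first_one = [t.first_cast for t in one]
    first_multi = [t.first_cast for t in multi]
    firsts = first_one + first_multi
    rep.first_cast_success_1cast = Rate(
        sum(1 for c in first_one if c.success), len(first_one))
    rep.first_cast_success_ncast = Rate(
        sum(1 for c in first_multi if c.success), len(first_multi))
    rep.first_cast_success_pooled = Rate(
        sum(1 for c in firsts if c.success), len(firsts))

    failed_first = [c for c in firsts if not c.success]
    succ_first = [c for c in firsts if c.success]
    rep.failed_first_rejected = Rate(
        sum(1 for c in failed_first if c.accepted is False), len(failed_first))
    rep.successful_first_accepted = Rate(
        sum(1 for c in succ_first if c.accepted), len(succ_first))

    seconds = [t.casts[1] for t in multi if t.n_casts >= 2]
    failed_second = [c for c in seconds if not c.success]
    succ_second = [c for c in seconds if c.success]
    rep.failed_second_rejected = Rate(
        sum(1 for c in failed_second if c.accepted is False), len(failed_second))
    rep.successful_second_accepted = Rate(
        sum(1 for c in succ_second if c.accepted), len(succ_second))

    # per-ordinal success within n-cast turns (1st, 2nd, >=3rd)
    for label, sel in (("1", lambda t: [t.casts[0]]),
                       ("2", lambda t: [t.casts[1]] if t.n_casts >= 2 else []),
                       ("3+", lambda t: t.casts[2:])):
        pool = [c for t in multi for c in sel(t)]
        rep.ncast_success_by_ordinal[label] = Rate(
            sum(1 for c in pool if c.success), len(pool))

    # amplitude samples by ordinal within n-cast turns (1st..5th+)
    amp: dict[str, list[float]] = {}
    for t in multi:
        for c in t.casts:
            amp.setdefault(_ordinal_bin(c.ordinal, 5), []).append(c.amplitude)
    rep.amplitude_by_ordinal = {k: amp[k] for k in sorted(amp)}

    rep.amplitude_failed_first_accepted = [
        c.amplitude for c in failed_first if c.accepted]
    rep.amplitude_failed_first_rejected = [
        c.amplitude for c in failed_first if c.accepted is False]
    rep.amplitude_failed_second_accepted = [
        c.amplitude for c in failed_second if c.accepted]
    rep.amplitude_failed_second_rejected = [
        c.amplitude for c in failed_second if c.accepted is False]
    if heading_pairs is not None:
        rep.heading_amplitude_first = list(heading_pairs[0])
        rep.heading_amplitude_second = list(heading_pairs[1])

    _attach_tests(rep)
    return rep


def _attach_tests(rep: SummaryReport) -> None:
    """Fisher / t-test comparisons mirroring the figure-level contrasts."""
    def fisher(name: str, r1: Rate, r2: Rate) -> None:
        try:
            rep.tests[name] = fisher_exact(Table2x2(
                r1.num, r1.den - r1.num, r2.num, r2.den - r2.num))
        except StatsError:
            pass

    fisher("success_1cast_vs_ncast", rep.success_1cast, rep.success_ncast)
    fisher("success_1cast_vs_overall", rep.success_1cast, rep.escape_overall)
    fisher("first_cast_success_1cast_vs_ncast",
           rep.first_cast_success_1cast, rep.first_cast_success_ncast)
    a1 = rep.amplitude_failed_first_accepted
    r1 = rep.amplitude_failed_first_rejected
    if len(a1) >= 2 and len(r1) >= 2:
        rep.tests["amplitude_failed_first_accepted_vs_rejected"] = students_t(a1, r1)[1]
    a2 = rep.amplitude_failed_second_accepted
    r2 = rep.amplitude_failed_second_rejected
    if len(a2) >= 2 and len(r2) >= 2:
        rep.tests["amplitude_failed_second_accepted_vs_rejected"] = students_t(a2, r2)[1]
    amp = rep.amplitude_by_ordinal
    if len(amp.get("1", [])) >= 2 and len(amp.get("2", [])) >= 2:
        rep.tests["amplitude_first_vs_second"] = students_t(amp["1"], amp["2"])[1]
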