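import itertools

import numpy as np
import pytest

import lightcast as lc
from lightcast.config import ConfigError
from lightcast.segmentation import (detect_head_casts, detect_stop_periods,
                                    label_acceptance, peakdet, segment_trajectory)


def peakdet_oracle(x, delta):
    """Brute-force delta-commit enumerator, structurally independent of peakdet.

    Repeatedly takes the argmax (argmin) of the growing candidate window
    and commits it once any later value drops (rises) delta past it.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = [], []
    mode = "max"
    anchor = 0
    while anchor < len(x):
        committed = False
        for j in range(anchor, len(x)):
            window = x[anchor:j + 1]
            if mode == "max":
                best = anchor + int(np.argmax(window))
                if x[j] < x[best] - delta:
                    maxima.append((best, x[best]))
                    anchor, mode, committed = j, "min", True
                    break
            else:
                best = anchor + int(np.argmin(window))
                if x[j] > x[best] + delta:
                    minima.append((best, x[best]))
                    anchor, mode, committed = j, "max", True
                    break
        if not committed:
            break
    return maxima, minima


def stop_oracle(ts, cfg):
    """Run-length + merge enumeration using itertools.groupby."""
    below = (np.asarray(ts) < cfg.tailspeed_stop_thresh).tolist()
    runs = []
    i = 0
    for val, grp in itertools.groupby(below):
        ln = len(list(grp))
        if val:
            runs.append((i, i + ln - 1))
        i += ln
    max_gap = int(round(cfg.max_stop_gap * cfg.frame_rate))
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    min_frames = int(round(cfg.min_stop_duration * cfg.frame_rate))
    return [r for r in merged if r[1] - r[0] + 1 >= min_frames]


class TestStopPeriods:
    def test_all_above_threshold_is_empty(self, cfg):
        assert detect_stop_periods(np.full(100, 1.0), cfg) == []

    def test_single_run_duration(self, cfg):
        ts = np.full(200, 1.0)
        ts[50:110] = 0.05
        stops = detect_stop_periods(ts, cfg)
        assert len(stops) == 1
        assert (stops[0].start_frame, stops[0].end_frame) == (50, 109)
        assert stops[0].duration == pytest.approx(1.0)

    def test_short_gap_merged(self, cfg):
        ts = np.full(300, 1.0)
        ts[50:100] = 0.05
        ts[103:150] = 0.05  # 3-frame excursion, under the 0.15 s gap
        stops = detect_stop_periods(ts, cfg)
        assert len(stops) == 1
        assert (stops[0].start_frame, stops[0].end_frame) == (50, 149)

    def test_matches_enumeration_oracle_on_random_series(self, cfg):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(5, 400)
            ts = rng.uniform(0, 0.5, n)
            got = [(s.start_frame, s.end_frame) for s in detect_stop_periods(ts, cfg)]
            assert got == stop_oracle(ts, cfg)

    def test_invariant_to_small_noise_far_from_threshold(self, cfg):
        rng = np.random.default_rng(13)
        base = np.where(np.sin(np.arange(400) / 15.0) > 0, 1.0, 0.05)
        ref = [(s.start_frame, s.end_frame) for s in detect_stop_periods(base, cfg)]
        for _ in range(20):
            noisy = base + rng.uniform(-0.02, 0.02, 400)  # < 10 % of threshold
            got = [(s.start_frame, s.end_frame) for s in detect_stop_periods(noisy, cfg)]
            assert got == ref


class TestPeakdet:
    def test_monotone_series_commits_nothing(self):
        assert peakdet(np.arange(50, dtype=float), 0.5) == ([], [])

    def test_simple_triangle(self):
        maxima, minima = peakdet(np.array([0.0, 1.0, 0.0]), 0.5)
        assert maxima == [(1, 1.0)]
        assert minima == []

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ConfigError):
            peakdet(np.zeros(5), 0.0)

    def test_extrema_alternate_in_time(self):
        rng = np.random.default_rng(21)
        x = np.cumsum(rng.normal(size=500))
        maxima, minima = peakdet(x, 1.0)
        events = sorted([(i, "max") for i, _ in maxima] + [(i, "min") for i, _ in minima])
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(300):
            n = int(rng.integers(3, 300))
            x = rng.normal(0, 1, n).cumsum() if rng.random() < 0.5 else rng.normal(0, 1, n)
            delta = float(10 ** rng.uniform(-2, 0.5))
            assert peakdet(x, delta) == peakdet_oracle(x, delta)


class TestHeadCasts:
    def test_flat_headomega_yields_nothing(self, cfg):
        n = 200
        kin = lc.KinematicSeries(
            headspeed=np.zeros(n), midspeed=np.zeros(n), tailspeed=np.zeros(n),
            cmspeed=np.zeros(n), headtheta=np.zeros(n), headomega=np.zeros(n),
            bodytheta=np.zeros(n), bodyomega=np.zeros(n))
        stops = [lc.StopPeriod(10, 180)]
        assert detect_head_casts(kin, stops, cfg) == []

    def test_single_scripted_cast(self, cfg, single_cast_trial):
        traj, truth = single_cast_trial
        kin = lc.compute_kinematics(traj, cfg)
        stops, casts = segment_trajectory(kin, cfg)
        assert len(stops) == 1
        assert len(casts) == 1
        cast = casts[0]
        scripted = truth.casts[0]
        assert abs(cast.peak_frame - scripted.peak_frame) <= 1
        assert abs(cast.amplitude - scripted.amplitude) / scripted.amplitude < 0.05
        # the detected end tracks the scripted return-to-zero; the smoothing
        # chain (position window + stencil + series window) delays the exact
        # zero of the filtered signal by up to its half-reach
        assert scripted.end_frame <= cast.end_frame <= scripted.end_frame + 25

    def test_straightening_pulse_excluded(self, cfg, nominal_spot):
        """A supra-threshold headomega peak that unbends the body is not a cast."""
        spec = lc.make_fixture("STRAIGHT", seed=0)
        (traj, _), = lc.simulate_fixture(spec, cfg)
        kin = lc.compute_kinematics(traj, cfg)
        stops, casts = segment_trajectory(kin, cfg)
        assert len(stops) == 1
        # pulse peak is scripted at 0.6 rad/s, well above threshold, yet excluded
        assert np.abs(kin.headomega[stops[0].start_frame:stops[0].end_frame]).max() > 0.35
        assert casts == []

    def test_casts_lie_inside_their_stop_and_do_not_overlap(self, cfg, f46):
        _, sims, result = f46
        for trial in result.trials:
            for si, stop in enumerate(trial.stops):
                sc = sorted((c for c in trial.casts if c.stop_index == si),
                            key=lambda c: c.start_frame)
                for c in sc:
                    assert stop.start_frame <= c.start_frame <= c.peak_frame <= c.end_frame
                    assert c.end_frame <= stop.end_frame
                    assert c.amplitude > cfg.headomega_peak_thresh
                for a, b in zip(sc, sc[1:]):
                    assert a.end_frame <= b.start_frame


class TestAcceptance:
    def _cast(self, ordinal, peak):
        return lc.HeadCast(stop_index=0, ordinal=ordinal, start_frame=peak - 5,
                           peak_frame=peak, end_frame=peak + 5, peak_omega=1.0)

    @pytest.mark.parametrize("n,expected", [
        (1, [True]),
        (2, [False, True]),
        (4, [False, False, False, True]),  # the 4-cast turn anatomy
    ])
    def test_all_but_last_rejected(self, n, expected):
        casts = [self._cast(i + 1, 10 * (i + 1)) for i in range(n)]
        labeled = label_acceptance(casts)
        assert [c.accepted for c in labeled] == expected

    def test_empty_input(self):
        assert label_acceptance([]) == []

    def test_exactly_one_accepted_per_stop_on_fixture(self, f46):
        _, _, result = f46
        for trial in result.trials:
            for si in range(len(trial.stops)):
                sc = [c for c in trial.casts if c.stop_index == si]
                if sc:
                    assert sum(c.accepted for c in sc) == 1
                    assert max(sc, key=lambda c: c.peak_frame).accepted
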