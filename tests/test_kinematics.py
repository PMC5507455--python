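import numpy as np
import pytest

import lightcast as lc
from lightcast.config import ConfigError
from lightcast.kinematics import (TrajectoryError, _central_diff, compute_bodytheta,
                                  compute_headtheta, compute_kinematics,
                                  compute_speed, differentiate_angle,
                                  moving_average)


def atan2_oracle(head, mid, tail):
    """Independent signed-angle oracle: atan2 of cross/dot of unit vectors."""
    u = (np.asarray(mid) - np.asarray(tail)).astype(float)
    v = (np.asarray(head) - np.asarray(mid)).astype(float)
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    return np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v)


class TestHeadTheta:
    @pytest.mark.parametrize("head,mid,tail,expect", [
        ((2, 0), (1, 0), (0, 0), 0.0),            # straight body
        ((1, 1), (1, 0), (0, 0), np.pi / 2),      # right-angle CCW bend
        ((1, -1), (1, 0), (0, 0), -np.pi / 2),    # mirrored bend, CW sign
    ])
    def test_known_angles(self, head, mid, tail, expect):
        assert compute_headtheta(head, mid, tail) == pytest.approx(expect)

    def test_matches_atan2_oracle_on_random_frames(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            tail, mid, head = rng.normal(0, 5, (3, 2))
            got = compute_headtheta(head, mid, tail)
            assert got == pytest.approx(atan2_oracle(head, mid, tail), abs=1e-12)
            assert -np.pi < got <= np.pi

    def test_degenerate_points_flagged_not_raised(self):
        assert np.isnan(compute_headtheta((1, 0), (1, 0), (0, 0)))

    def test_rotation_equivariance(self):
        """Rotating all points leaves headtheta unchanged, shifts bodytheta."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            tail, mid, head = rng.normal(0, 5, (3, 2))
            phi = rng.uniform(-np.pi, np.pi)
            rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            h0 = compute_headtheta(head, mid, tail)
            h1 = compute_headtheta(rot @ head, rot @ mid, rot @ tail)
            assert h1 == pytest.approx(h0, abs=1e-9)
            b0 = compute_bodytheta(mid, tail)
            b1 = compute_bodytheta(rot @ mid, rot @ tail)
            diff = (b1 - b0 - phi + np.pi) % (2 * np.pi) - np.pi
            assert diff == pytest.approx(0.0, abs=1e-9)


class TestBodyTheta:
    @pytest.mark.parametrize("mid,tail,expect", [
        ((1, 0), (0, 0), 0.0),
        ((0, 1), (0, 0), np.pi / 2),
        ((-1, 1), (0, 0), 3 * np.pi / 4),
    ])
    def test_known_angles(self, mid, tail, expect):
        assert compute_bodytheta(mid, tail) == pytest.approx(expect)


class TestSpeed:
    def test_stationary_is_zero(self):
        pts = np.tile([3.0, 4.0], (50, 1))
        assert np.allclose(compute_speed(pts, 60.0, 11.94), 0.0)

    def test_uniform_motion_matches_calibration(self):
        # 11.94 px per frame at 60 fps and 11.94 px/mm is 60 mm/s
        pts = np.column_stack([11.94 * np.arange(40), np.zeros(40)])
        v = compute_speed(pts, 60.0, 11.94)
        assert np.allclose(v, 60.0)

    def test_random_walk_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 2, (80, 2)), axis=0)
        v = compute_speed(pts, 60.0, 11.94, stencil=1)
        # brute-force per-frame differencing
        for i in range(1, 79):
            d = np.linalg.norm(pts[i + 1] - pts[i - 1]) / (2 / 60.0) / 11.94
            assert v[i] == pytest.approx(d, abs=1e-9)
        assert v[0] == pytest.approx(
            np.linalg.norm(pts[1] - pts[0]) * 60.0 / 11.94, abs=1e-9)

    def test_invariance_under_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(0, 2, (60, 2)), axis=0)
        phi = 1.1
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = pts @ rot.T + np.array([100.0, -50.0])
        assert np.allclose(compute_speed(pts, 60, 11.94, 5),
                           compute_speed(moved, 60, 11.94, 5), atol=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(TrajectoryError):
            compute_speed(np.zeros((1, 2)), 60.0, 11.94)


class TestDifferentiateAngle:
    def test_constant_is_zero(self):
        assert np.allclose(differentiate_angle(np.full(30, 0.7), 60.0), 0.0)

    def test_linear_ramp_recovers_slope_everywhere(self):
        # ramp at the head-cast threshold rate, 0.35 rad/s
        theta = 0.35 / 60.0 * np.arange(100)
        for k in (1, 3, 8):
            omega = differentiate_angle(theta, 60.0, stencil=k)
            assert np.allclose(omega, 0.35, atol=1e-12)

    def test_wrap_crossing_is_continuous(self):
        t = np.arange(200) / 60.0
        theta_true = 2.9 + 0.5 * t          # crosses +pi
        wrapped = (theta_true + np.pi) % (2 * np.pi) - np.pi
        omega = differentiate_angle(wrapped, 60.0)
        oracle = _central_diff(np.unwrap(wrapped), 1 / 60.0, 1)
        assert np.allclose(omega, oracle, atol=1e-12)
        assert np.allclose(omega[1:-1], 0.5, atol=1e-9)


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=25)
        assert np.array_equal(moving_average(x, 1), x)

    def test_constant_preserved(self):
        assert np.allclose(moving_average(np.full(11, 2.5), 5), 2.5)

    def test_impulse(self):
        got = moving_average(np.array([0.0, 0, 1, 0, 0]), 3)
        assert np.allclose(got, [0, 1 / 3, 1 / 3, 1 / 3, 0])

    def test_mean_preserved_on_interior(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=101)
        sm = moving_average(x, 9)
        # interior of the smoothed series redistributes mass only locally
        assert sm[4:-4].mean() == pytest.approx(x.mean(), abs=0.1)

    @pytest.mark.parametrize("window", [0, 2, 4, 999])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ConfigError):
            moving_average(np.zeros(10), window)


class TestFullKinematics:
    def test_all_stationary_trajectory(self, cfg):
        n = 40
        traj = lc.Trajectory(frame_index=np.arange(n),
                             head=np.tile([2.0, 0.0], (n, 1)),
                             mid=np.tile([1.0, 0.0], (n, 1)),
                             tail=np.tile([0.0, 0.0], (n, 1)),
                             centroid=np.tile([1.0, 0.0], (n, 1)))
        kin = compute_kinematics(traj, cfg)
        for series in (kin.headspeed, kin.tailspeed, kin.headomega, kin.bodyomega):
            assert np.allclose(series, 0.0, atol=1e-12)
        assert np.allclose(kin.headtheta, 0.0, atol=1e-12)

    def test_straight_run_has_flat_headtheta_and_scripted_tailspeed(self, cfg, nominal_spot):
        from lightcast.synthetic import TrialScript, simulate_trial
        traj, _ = simulate_trial(TrialScript(run_only_s=3.0), nominal_spot, cfg)
        kin = compute_kinematics(traj, cfg)
        assert np.allclose(kin.headtheta, 0.0, atol=1e-9)
        # scripted run speed 1.5 mm/s with +-0.1 ripple, recovered within 5 %
        interior = kin.tailspeed[20:-20]
        assert abs(interior.mean() - 1.5) / 1.5 < 0.05

    def test_scripted_cast_peak_recovered_within_5_percent(self, cfg, nominal_spot,
                                                           single_cast_trial):
        traj, truth = single_cast_trial
        kin = compute_kinematics(traj, cfg)
        above = np.abs(kin.headomega) > 0.35
        # exactly one contiguous supra-threshold interval
        edges = np.flatnonzero(np.diff(above.astype(int)))
        assert len(edges) == 2
        peak = np.abs(kin.headomega).max()
        scripted = truth.casts[0].amplitude
        assert abs(peak - scripted) / scripted < 0.05

    def test_speeds_are_nonnegative_and_lengths_match(self, f46):
        _, sims, _ = f46
        traj, _ = sims[0]
        kin = compute_kinematics(traj)
        n = traj.n_frames
        for s in (kin.headspeed, kin.midspeed, kin.tailspeed, kin.cmspeed):
            assert len(s) == n and (s >= 0).all()
        assert len(kin.headomega) == len(kin.bodyomega) == len(kin.headtheta) == n
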