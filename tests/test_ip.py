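"""Inverted-pendulum estimator: Kalman smoothing, balance solution,
acceleration transfer, and the fixed-point reconstruction loop."""

import numpy as np
import pytest
from scipy.optimize import brentq

from skipose.errors import DataError, NoSolutionError
from skipose.ip import (InvertedPendulumEstimator, balance_residual,
                        com_accel_from_antenna, estimate_ip, kalman_theta,
                        solve_theta, solve_theta_series)
from skipose.simulate import CourseSpec, SkierSpec, make_course, make_run


class TestKalmanTheta:
    def test_quadratic_signal_acceleration(self):
        """θ = 0.1 t² has θ̈ = 0.2; the smoother recovers it in the interior."""
        dt = 1 / 120
        t = np.arange(0, 5, dt)
        _, _, tdd = kalman_theta(0.1 * t ** 2, dt)
        inner = tdd[120:-120]
        np.testing.assert_allclose(inner, 0.2, atol=1e-3)

    def test_constant_signal_zero_derivatives(self):
        dt = 1 / 120
        th, td, tdd = kalman_theta(np.full(600, 0.4), dt)
        assert np.max(np.abs(td)) < 1e-6
        assert np.max(np.abs(tdd)) < 1e-6
        np.testing.assert_allclose(th, 0.4, atol=1e-9)

    def test_noisy_sinusoid_acceleration_rmse(self, rng):
        """θ = 0.3 sin(2t) + N(0, 0.01): θ̈ RMSE < 0.15 rad/s² vs analytic.

        r matches the noise variance; q is set near the signal's actual
        jerk power (amplitude 2.4 rad/s³) rather than the permissive
        estimator default."""
        dt = 1 / 120
        t = np.arange(0, 10, dt)
        y = 0.3 * np.sin(2 * t) + rng.normal(0, 0.01, t.size)
        _, _, tdd = kalman_theta(y, dt, q=1.0, r_meas=1e-4)
        truth = -1.2 * np.sin(2 * t)
        rmse = np.sqrt(np.mean((tdd[60:-60] - truth[60:-60]) ** 2))
        assert rmse < 0.15

    def test_nonuniform_or_short_input_rejected(self):
        with pytest.raises(DataError):
            kalman_theta(np.zeros(5), 0.01)
        with pytest.raises(DataError):
            kalman_theta(np.zeros(100), -0.01)


def _eq2(theta, a_r, a_z, tdd, l_g, g=9.81):
    return l_g * tdd + a_r * np.cos(theta) - (a_z + g) * np.sin(theta)


class TestSolveTheta:
    def test_static_45_degrees(self):
        """a_r = g, a_z = 0, θ̈ = 0: tanθ = 1."""
        assert solve_theta(9.81, 0.0, 0.0, 1.0) == pytest.approx(np.pi / 4,
                                                                 abs=1e-12)

    def test_rest_is_upright(self):
        assert solve_theta(0.0, 0.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_against_bracketing_root(self):
        """a_r=5, a_z=1, θ̈=0.3, l_g=1, checked against brentq on the
        balance equation."""
        th = solve_theta(5.0, 1.0, 0.3, 1.0)
        assert abs(_eq2(th, 5.0, 1.0, 0.3, 1.0)) < 1e-9
        ref = brentq(lambda x: _eq2(x, 5.0, 1.0, 0.3, 1.0),
                     -np.pi / 2 + 1e-9, np.pi / 2 - 1e-9, xtol=1e-14)
        assert th == pytest.approx(ref, abs=1e-9)

    def test_random_draws_satisfy_balance_equation(self, rng):
        """1000 random draws from the solvable domain (an upright root is
        guaranteed when |l_g·θ̈| < a_z + g, which is also the bracketing
        condition): residual < 1e-9.  The full 10⁴-draw cross-check against
        brentq runs in the acceptance suite."""
        n = 1000
        a_r = rng.uniform(-15, 15, n)
        a_z = rng.uniform(-5, 8, n)
        l_g = rng.uniform(0.5, 1.2, n)
        tdd = rng.uniform(-0.95, 0.95, n) * (a_z + 9.81) / l_g
        th = solve_theta_series(a_r, a_z, tdd, l_g)
        res = balance_residual(th, a_r, a_z, tdd, l_g)
        assert np.max(np.abs(res)) < 1e-9
        assert np.all(np.abs(th) < np.pi / 2)

    def test_negative_discriminant_raises(self):
        with pytest.raises(NoSolutionError):
            solve_theta(0.1, 0.0, 100.0, 1.0)

    def test_quasistatic_fallback(self):
        """Large θ̈ against a weak restoring acceleration leaves no upright
        root; the fallback substitutes the clipped θ̈=0 lean."""
        args = ([2.83], [-9.299], [1.844], [1.08])
        with pytest.raises(NoSolutionError):
            solve_theta_series(*args)
        th = solve_theta_series(*args, on_unsolvable="quasistatic")
        assert np.abs(th[0]) <= np.pi / 2


class TestComAccelTransfer:
    def test_static_pendulum_identity(self):
        n = 50
        a_r, a_z = com_accel_from_antenna(
            np.full(n, 2.0), np.full(n, -1.0), np.full(n, 0.3),
            np.full(n, 1.4), 0.56,
            theta_dot=np.zeros(n), theta_ddot=np.zeros(n),
            l_dot=np.zeros(n), l_ddot=np.zeros(n))
        np.testing.assert_allclose(a_r, 2.0, atol=1e-12)
        np.testing.assert_allclose(a_z, -1.0, atol=1e-12)

    def test_pure_rotation_centripetal_magnitude(self):
        """Fixed l, constant θ̇: relative acceleration = (1−k)·l·θ̇²."""
        n, k, l, td = 50, 0.56, 1.4, 0.8
        theta = np.full(n, 0.2)
        a_r, a_z = com_accel_from_antenna(
            np.zeros(n), np.zeros(n), theta, np.full(n, l), k,
            theta_dot=np.full(n, td), theta_ddot=np.zeros(n),
            l_dot=np.zeros(n), l_ddot=np.zeros(n))
        mag = np.hypot(a_r, a_z)
        np.testing.assert_allclose(mag, (1 - k) * l * td ** 2, rtol=1e-12)

    def test_matches_finite_difference_oracle(self):
        """Synthetic smooth θ(t), l(t): the analytic transfer matches second
        finite differences of the analytically placed antenna and COM points
        to < 1e-3 m/s² at 120 Hz."""
        dt = 1 / 120
        t = np.arange(0, 6, dt)
        k = 0.56
        theta = 0.5 * np.sin(1.3 * t) + 0.1
        l = 1.4 + 0.08 * np.sin(0.7 * t + 0.3)
        # place points in the (radial, vertical) lean plane
        u = np.column_stack([np.sin(theta), np.cos(theta)])
        base = np.column_stack([0.3 * t ** 2, 0.1 * t])  # arbitrary smooth base
        antenna = base + l[:, None] * u
        com = base + (k * l)[:, None] * u
        def fd2(x):
            return np.gradient(np.gradient(x, dt, axis=0), dt, axis=0)
        a_ant = fd2(antenna)
        a_com_fd = fd2(com)
        theta_dot = np.gradient(theta, dt)
        theta_ddot = np.gradient(theta_dot, dt)
        l_dot = np.gradient(l, dt)
        l_ddot = np.gradient(l_dot, dt)
        a_r, a_z = com_accel_from_antenna(
            a_ant[:, 0], a_ant[:, 1], theta, l, k,
            theta_dot=theta_dot, theta_ddot=theta_ddot,
            l_dot=l_dot, l_ddot=l_ddot)
        sl = slice(5, -5)
        np.testing.assert_allclose(a_r[sl], a_com_fd[sl, 0], atol=1e-3)
        np.testing.assert_allclose(a_z[sl], a_com_fd[sl, 1], atol=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            com_accel_from_antenna(np.zeros(5), np.zeros(4), np.zeros(5),
                                   np.ones(5), 0.56, dt=0.01)


class TestEstimateIP:
    def test_balanced_run_com_recovery(self, default_world, default_skier,
                                       balanced_run):
        """Noise-free balanced run: COM RMS error < 0.02 m."""
        mesh, _ = default_world
        res = estimate_ip(balanced_run.antenna_trajectory(), mesh)
        assert res.converged
        err = np.linalg.norm(res.pendulum.com - balanced_run.com, axis=1)
        assert np.sqrt(np.mean(err ** 2)) < 0.02

    def test_converges_within_ten_iterations(self, default_world,
                                             balanced_run):
        mesh, _ = default_world
        res = estimate_ip(balanced_run.antenna_trajectory(), mesh)
        assert res.converged and res.n_iterations <= 10

    def test_residual_non_increasing_after_second_iteration(
            self, default_world, balanced_run):
        mesh, _ = default_world
        res = estimate_ip(balanced_run.antenna_trajectory(), mesh)
        tail = res.residuals[1:]
        assert all(b <= a + 1e-12 for a, b in zip(tail, tail[1:]))

    def test_straight_fall_line_degenerate_case(self, default_skier):
        """Straight balanced run: θ constant (zero) and the ground point
        tracks the simulator's ground to ±0.01 m."""
        course = CourseSpec(n_gates=2, gate_lateral_offset_m=0.0)
        mesh, gates = make_course(course)
        run = make_run((mesh, gates), default_skier, speed_spec=course)
        res = estimate_ip(run.antenna_trajectory(), mesh)
        assert np.max(np.abs(res.pendulum.theta)) < 1e-3
        err = np.linalg.norm(res.pendulum.ground - run.mid_ski(), axis=1)
        assert np.max(err) < 0.01

    def test_ground_point_on_mesh(self, default_world, default_course,
                                  balanced_run):
        mesh, _ = default_world
        res = estimate_ip(balanced_run.antenna_trajectory(), mesh)
        g = res.pendulum.ground
        surface_z = -np.tan(default_course.pitch) * g[:, 0]
        assert np.max(np.abs(g[:, 2] - surface_z)) < 1e-5

    def test_sklearn_param_interface(self):
        est = InvertedPendulumEstimator(k=0.55)
        params = est.get_params()
        assert params["k"] == 0.55
        est.set_params(k=0.57, tol=1e-4)
        assert est.k == 0.57 and est.tol == 1e-4

    def test_short_or_nonuniform_input_rejected(self, flat_mesh):
        t = np.arange(0, 1, 0.05)
        from skipose.trajio import Trajectory3D
        tr = Trajectory3D(t, np.column_stack([t, t, np.ones_like(t)]))
        with pytest.raises(DataError):
            estimate_ip(tr, flat_mesh)  # under 3 s of data
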