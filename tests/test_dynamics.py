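"""Vector-field oracles, integrator convergence, and the seizure threshold."""

import numpy as np
import pytest
from scipy.integrate import quad

from epimap import dynamics as dyn


def single_node_5d(x0=-3.0, K=0.0):
    return dyn.Epileptor5DParams(x0=np.array([x0]), K=K, C=np.zeros((1, 1)))


def single_node_2d(x0=-3.0, tau0=20.0):
    return dyn.Epileptor2DParams(x0=np.array([x0]), K=0.0,
                                 C=np.zeros((1, 1)), tau0=tau0)


class TestDerivatives5D:
    def test_fast_subsystem_hand_values(self):
        """f1 cubic branch and the y1 equation evaluated by hand."""
        p = single_node_5d()
        state = np.array([[-1.0], [1.0], [0.0], [-0.3], [0.0], [0.0]])
        d = dyn.derivatives_5d(state, p)
        # f1(-1) = (-1)^3 - 3(-1)^2 = -4, so dx1 = y1 - f1 - z + I1 = 8.1
        assert d[0, 0] == pytest.approx(8.1)
        # dy1 = 1 - 5 x1^2 - y1 = 1 - 5 - 1
        assert d[1, 0] == pytest.approx(-5.0)

    @pytest.mark.parametrize("x2,expected_f2", [(-0.3, 0.0), (0.0, 1.5)])
    def test_f2_branches(self, x2, expected_f2):
        """f2 is zero below -0.25 and 6(x2+0.25) above."""
        p = single_node_5d()
        state = np.array([[-1.0], [0.0], [0.0], [x2], [0.0], [0.0]])
        d = dyn.derivatives_5d(state, p)
        # dy2 = (f2 - y2)/tau2 with y2 = 0
        assert d[4, 0] == pytest.approx(expected_f2 / p.tau2)

    def test_f1_upper_branch_uses_x2_and_z(self):
        """For x1 >= 0 the fast nullcline couples to x2 and z."""
        p = single_node_5d()
        x1, x2, z, y1 = 0.5, -0.3, 4.0, 0.2
        state = np.array([[x1], [y1], [z], [x2], [0.0], [0.0]])
        d = dyn.derivatives_5d(state, p)
        f1 = (x2 - 0.6 * (z - 4.0) ** 2) * x1
        assert d[0, 0] == pytest.approx(y1 - f1 - z + p.I1)

    def test_nonfinite_state_raises(self):
        p = single_node_5d()
        state = np.full((6, 1), np.nan)
        with pytest.raises(dyn.DivergenceError):
            dyn.derivatives_5d(state, p)


class TestDerivatives2D:
    def test_hand_value_single_node(self):
        p = single_node_2d(x0=-3.0)
        dx, dz = dyn.derivatives_2d(np.array([-2.0]), np.array([4.0]), p)
        # dx = 1 + 8 - 8 - 4 + 3.1 ; dz = (4*1 - 4)/20
        assert dx[0] == pytest.approx(0.1)
        assert dz[0] == pytest.approx(0.0)

    def test_uniform_state_kills_coupling(self):
        """With equal x everywhere the permittivity coupling vanishes."""
        n = 5
        rng = np.random.default_rng(0)
        C = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(C, 0)
        p = dyn.Epileptor2DParams(x0=np.full(n, -2.5), K=3.0, C=C)
        x = np.full(n, -1.7)
        z = rng.uniform(2, 4, n)
        _, dz = dyn.derivatives_2d(x, z, p)
        p0 = dyn.Epileptor2DParams(x0=np.full(n, -2.5), K=0.0, C=C)
        _, dz0 = dyn.derivatives_2d(x, z, p0)
        np.testing.assert_allclose(dz, dz0, rtol=1e-12)

    def test_fixed_point_zeroes_both_derivatives(self):
        x_star, z_star = dyn.fixed_point_2d(-3.0)
        p = single_node_2d(-3.0)
        dx, dz = dyn.derivatives_2d(np.array([x_star]), np.array([z_star]), p)
        assert abs(dx[0]) < 1e-9
        assert abs(dz[0]) < 1e-9

    def test_coupling_antisymmetry_two_nodes(self):
        """Symmetric C: the coupling contributions to the two dz are equal
        and opposite."""
        C = np.array([[0.0, 0.7], [0.7, 0.0]])
        x0 = np.array([-2.0, -3.0])
        x = np.array([-1.2, -2.1])
        z = np.array([3.0, 3.4])
        pK = dyn.Epileptor2DParams(x0=x0, K=2.0, C=C, tau0=20.0)
        p0 = dyn.Epileptor2DParams(x0=x0, K=0.0, C=C, tau0=20.0)
        _, dzK = dyn.derivatives_2d(x, z, pK)
        _, dz0 = dyn.derivatives_2d(x, z, p0)
        contrib = (dzK - dz0) * 20.0
        assert contrib[0] == pytest.approx(-contrib[1])


class TestIntegrators:
    def test_heun_single_step_hand_value(self):
        traj = dyn.integrate_heun(lambda y: -y, np.array([1.0]), 0.1, 0.1)
        assert traj.states[-1, 0] == pytest.approx(0.905)

    def test_rk4_single_step_matches_exponential(self):
        traj = dyn.integrate_rk4(lambda y: -y, np.array([1.0]), 0.1, 1)
        assert traj.states[-1, 0] == pytest.approx(np.exp(-0.1), abs=1e-6)

    @pytest.mark.parametrize("integrate,order", [
        (lambda f, y0, dt, n: dyn.integrate_heun(f, y0, dt, n * dt), 2),
        (lambda f, y0, dt, n: dyn.integrate_rk4(f, y0, dt, n), 4),
    ], ids=["heun", "rk4"])
    def test_order_of_convergence(self, integrate, order):
        """Halving dt divides the global error by about 2^order."""
        def err(dt):
            n = int(round(1.0 / dt))
            traj = integrate(lambda y: -y, np.array([1.0]), dt, n)
            return abs(traj.states[-1, 0] - np.exp(-1.0))

        ratio = err(0.1) / err(0.05)
        assert ratio == pytest.approx(2 ** order, rel=0.15)

    def test_zero_field_keeps_state(self):
        y0 = np.array([2.0, -1.0])
        traj = dyn.integrate_heun(lambda y: np.zeros_like(y), y0, 0.1, 1.0)
        np.testing.assert_array_equal(traj.states[-1], y0)
        traj = dyn.integrate_rk4(lambda y: np.zeros_like(y), y0, 0.1, 10)
        np.testing.assert_array_equal(traj.states[-1], y0)

    def test_integrators_are_deterministic(self):
        p = single_node_2d(-2.0)
        f = lambda y: np.stack(dyn.derivatives_2d(y[0], y[1], p))
        y0 = np.array([[-2.0], [3.5]])
        a = dyn.integrate_heun(f, y0, 0.05, 50.0)
        b = dyn.integrate_heun(f, y0, 0.05, 50.0)
        np.testing.assert_array_equal(a.states, b.states)

    def test_divergence_carries_step_index(self):
        with pytest.raises(dyn.DivergenceError) as err:
            dyn.integrate_heun(lambda y: y ** 2, np.array([5.0]), 0.5, 50.0)
        assert err.value.step > 0

    def test_rk4_and_heun_agree_on_coupled_network(self):
        C = np.array([[0.0, 0.5], [0.5, 0.0]])
        p = dyn.Epileptor2DParams(x0=np.array([-2.0, -2.5]), K=1.0, C=C,
                                  tau0=20.0)
        f = lambda y: np.stack(dyn.derivatives_2d(y[0], y[1], p))
        y0 = np.array([[-1.8, -2.0], [3.2, 3.5]])
        n = 5000
        a = dyn.integrate_heun(f, y0, 1e-3, n * 1e-3, record_every=n)
        b = dyn.integrate_rk4(f, y0, 1e-3, n, record_every=n)
        assert np.max(np.abs(a.states[-1] - b.states[-1])) < 1e-3

    def test_auxiliary_state_tracks_convolution(self):
        """u(t) must match direct quadrature of the exponential-decay
        convolution of x1 on a 1-node run."""
        p = single_node_5d(x0=-2.0)  # drifts, so x1 is nonconstant
        init = dyn.fixed_point_5d(-3.0, p)
        init[5] = 0.0  # u(0) = 0 so the convolution starts empty
        traj = dyn.integrate_heun(
            lambda s: dyn.derivatives_5d(s, p), init.reshape(6, 1),
            dt=0.05, duration=100.0, record_every=4)
        t = traj.times
        x1 = traj.states[:, 0, 0]
        u = traj.states[:, 5, 0]
        t_end = t[-1]
        integrand = lambda tau: np.exp(-p.gamma * (t_end - tau)) * \
            np.interp(tau, t, x1)
        expected, _ = quad(integrand, 0.0, t_end, limit=200)
        assert u[-1] == pytest.approx(expected, rel=0.01)


class TestSeizureThreshold:
    def test_bisection_matches_linear_stability(self):
        """Simulation-based bisection agrees with the closed-form loss of
        stability of the isolated-node fixed point."""
        est = dyn.estimate_seizure_threshold_2d(tol=1e-3)
        analytic = dyn.seizure_threshold_linear_stability(20.0)
        assert est == pytest.approx(analytic, abs=0.02)
        assert est >= -2.1  # printed bifurcation bound

    def test_scenario_excitabilities_straddle_threshold(self):
        assert dyn._node_seizes(-1.8, 20.0, 3.1, 0.1, 1000.0, 0.0)
        assert not dyn._node_seizes(-3.0, 20.0, 3.1, 0.1, 1000.0, 0.0)

    def test_classification_monotone_in_x0(self):
        values = [-3.0, -2.6, -2.2, -2.049, -1.9, -1.5]
        seizing = [dyn._node_seizes(v, 20.0, 3.1, 0.1, 1000.0, 0.0)
                   for v in values]
        # once seizing, always seizing for larger x0
        assert seizing == sorted(seizing)

    def test_non_bracketing_interval_raises(self):
        with pytest.raises(ValueError):
            dyn.estimate_seizure_threshold_2d(search_interval=(-4.0, -3.0))


class TestFixedPoints:
    def test_no_stable_fixed_point_above_threshold(self):
        with pytest.raises(ValueError):
            dyn.fixed_point_2d(-1.5)

    def test_5d_fixed_point_is_stationary(self):
        p = single_node_5d(-3.0)
        fp = dyn.fixed_point_5d(-3.0, p)
        d = dyn.derivatives_5d(fp.reshape(6, 1), p)
        assert np.max(np.abs(d)) < 1e-8

    def test_clamped_rest_state_is_stationary_except_z(self):
        p = single_node_5d(-3.0)
        fp = dyn.fixed_point_5d(-3.0, p, z_value=3.5)
        assert fp[2] == 3.5
        d = dyn.derivatives_5d(fp.reshape(6, 1), p).ravel()
        assert np.max(np.abs(d[[0, 1, 3, 4, 5]])) < 1e-8


class TestTrajectory:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            dyn.Trajectory(times=np.array([0.0, 0.0]),
                           states=np.zeros((2, 1)))

    def test_npz_roundtrip(self, tmp_path):
        traj = dyn.integrate_rk4(lambda y: -y, np.array([1.0]), 0.1, 5)
        path = tmp_path / "traj.npz"
        traj.save_npz(path)
        back = dyn.Trajectory.load_npz(path)
        np.testing.assert_array_equal(back.states, traj.states)
        np.testing.assert_array_equal(back.times, traj.times)
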