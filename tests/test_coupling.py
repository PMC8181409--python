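"""Real, complex and power coupling; normalized phase differences;
steady-state detection; basin scans."""

import numpy as np
import pytest

from hopfnet import (NetworkConfig, OscillatorParams, OscillatorState,
                     basin_scan, cluster_solutions, coupling_drive,
                     detect_steady_state, normalized_phase, sigma_deviation,
                     simulate_kuramoto, simulate_network)
from hopfnet.coupling import _simulate_batch

TWO_PI = 2 * np.pi


class TestCouplingDrive:
    def test_real_coupling_ignores_imaginary_part(self):
        states = [OscillatorState(), OscillatorState(r=1.0, phi=np.pi / 2)]
        A = np.array([[0.0, 0.5], [0.0, 0.0]])
        th = np.zeros((2, 2))
        drive = coupling_drive(states, [5.0, 5.0], (A, th), "real", 0)
        assert abs(drive) < 1e-12

    def test_complex_identity_weight(self):
        states = [OscillatorState(), OscillatorState(r=1.0, phi=0.0)]
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        th = np.zeros((2, 2))
        drive = coupling_drive(states, [5.0, 5.0], (A, th), "complex", 0)
        assert drive == pytest.approx(1.0 + 0.0j)

    def test_power_integer_multiple_phase(self):
        # r=1, phi=pi, w_i/w_j = 2 -> exp(2*pi*i) = 1
        states = [OscillatorState(), OscillatorState(r=1.0, phi=np.pi)]
        A = np.array([[0.0, 1.0], [0.0, 0.0]])
        th = np.zeros((2, 2))
        drive = coupling_drive(states, [10.0, 5.0], (A, th), "power", 0)
        assert drive == pytest.approx(1.0 + 0.0j, abs=1e-12)

    def test_power_rejects_nonpositive_omega(self):
        states = [OscillatorState(), OscillatorState()]
        A = np.ones((2, 2))
        with pytest.raises(ValueError):
            coupling_drive(states, [5.0, 0.0], (A, np.zeros((2, 2))), "power", 0)


class TestComplexPair:
    THETA = np.pi / 4

    def _run(self, psi0, A=0.5, mu=1.0, duration=100.0):
        cfg = NetworkConfig.pair("complex", mu, [5.0, 5.0], A, self.THETA)
        return simulate_network(cfg, state0=(np.ones(2), np.array([psi0, 0.0])),
                                duration=duration, stride=100)

    @pytest.mark.parametrize("psi0", np.linspace(np.pi / 4 - np.pi + 0.15,
                                                 np.pi / 4 + np.pi - 0.15, 24))
    def test_principal_basin_locks_at_theta(self, psi0):
        traj = self._run(psi0)
        psi = traj.phi[-1, 0] - traj.phi[-1, 1]
        assert psi == pytest.approx(self.THETA, abs=0.01)

    def test_alternate_basin_locks_at_2pi_plus_theta(self):
        traj = self._run(self.THETA + np.pi + 0.2)
        psi = traj.phi[-1, 0] - traj.phi[-1, 1]
        assert psi == pytest.approx(TWO_PI + self.THETA, abs=0.01)

    @pytest.mark.parametrize("A", [0.1, 0.5])
    def test_locked_radius_sqrt_mu_plus_A(self, A):
        traj = self._run(0.0, A=A, duration=200.0)
        expected = np.sqrt(1.0 + A)
        assert traj.r[-1, 0] == pytest.approx(expected, abs=1e-3)
        assert traj.r[-1, 1] == pytest.approx(expected, abs=1e-3)


class TestRealPair:
    def test_equal_omega_locks_in_or_out_of_phase(self):
        for psi0, theta in [(0.5, 0.0), (2.5, np.pi)]:
            cfg = NetworkConfig.pair("real", 1.0, [5.0, 5.0], 0.2, theta,
                                     hermitian=False)
            traj = simulate_network(cfg, state0=(np.ones(2),
                                                 np.array([psi0, 0.0])),
                                    duration=200.0, stride=100)
            psi = (traj.phi[-1, 0] - traj.phi[-1, 1]) % TWO_PI
            dist0 = min(psi, TWO_PI - psi)
            dist_pi = abs(psi - np.pi)
            assert min(dist0, dist_pi) < 0.05


class TestPowerPair:
    def test_fig6a_normalized_phase_lock(self):
        cfg = NetworkConfig.pair("power", 1.0, [5.0, 10.0], 0.05, -1.8968)
        traj = simulate_network(cfg,
                                state0=(np.ones(2), np.array([3.7008, 2.3106])),
                                duration=200.0, stride=100)
        psi = normalized_phase(traj, 0, 1)
        assert psi[-1] == pytest.approx(-0.038, abs=2e-3)

    def test_weak_coupling_free_rotation(self):
        cfg = NetworkConfig.pair("power", 1.0, [5.0, 10.0], 1e-4, 1.0)
        phi0 = np.array([0.7, 1.9])
        traj = simulate_network(cfg, state0=(np.ones(2), phi0),
                                duration=100.0, stride=10)
        for i, w in enumerate((5.0, 10.0)):
            drift = traj.phi[:, i] - w * traj.t - phi0[i]
            assert np.max(np.abs(drift)) < 0.05

    def test_decoupled_phase_difference_constant(self):
        cfg = NetworkConfig.pair("power", 1.0, [5.0, 10.0], 0.0, 0.0)
        phi0 = np.array([1.0, 2.0])
        traj = simulate_network(cfg, state0=(np.ones(2), phi0), duration=50.0)
        psi = normalized_phase(traj, 0, 1)
        assert psi[-1] == pytest.approx(psi[0], abs=1e-9)


class TestKuramoto:
    def test_locked_frequency_closed_form(self):
        cfg = NetworkConfig(N=2, coupling_kind="real",
                            params=[OscillatorParams.supercritical(1.0, w)
                                    for w in (5.0, 6.0)],
                            weights=(np.array([[0.0, 1.0], [1.0, 0.0]]),
                                     np.zeros((2, 2))))
        traj = simulate_kuramoto(cfg, kind="real", duration=50.0,
                                 phi0=[[0.0, 0.5]])
        n = max(2, int(10.0 / traj.dt))
        w_lock = (traj.phi[-1] - traj.phi[-n]) / (traj.t[-1] - traj.t[-n])
        expected = (1.0 * 6.0 + 1.0 * 5.0) / 2.0
        assert np.allclose(w_lock, expected, atol=0.01)
        psi = traj.phi[-1, 0] - traj.phi[-1, 1]
        assert np.sin(psi) == pytest.approx((5.0 - 6.0) / 2.0, rel=0.01)

    def test_weak_coupling_never_locks(self):
        K = np.array([[0.0, 0.4], [0.4, 0.0]])  # K1+K2 < |w1-w2|
        cfg = NetworkConfig(N=2, coupling_kind="real",
                            params=[OscillatorParams.supercritical(1.0, w)
                                    for w in (5.0, 6.0)],
                            weights=(K, np.zeros((2, 2))))
        traj = simulate_kuramoto(cfg, kind="real", duration=100.0)
        psi = traj.phi[:, 0] - traj.phi[:, 1]
        assert abs(psi[-1] - psi[0]) > 10.0

    def test_power_kuramoto_desired_solution_is_fixed(self):
        w1, w2, theta = 5.0, 10.0, 0.5
        cfg = NetworkConfig.pair("power", 1.0, [w1, w2], 0.2, theta)
        psi_star = theta / (w1 * w2)
        traj = simulate_kuramoto(cfg, kind="power", duration=50.0,
                                 phi0=[[psi_star * w1, 0.0]])
        psi = traj.phi[:, 0] / w1 - traj.phi[:, 1] / w2
        assert np.max(np.abs(psi - psi_star)) < 1e-6


class TestNormalizedPhase:
    def test_closed_form(self):
        cfg = NetworkConfig.pair("power", 1.0, [np.pi, 2.0], 0.0, 0.0)
        traj = simulate_network(cfg, state0=(np.ones(2),
                                             np.array([np.pi, 0.0])),
                                duration=0.01, stride=1)
        assert normalized_phase(traj, 0, 1)[0] == pytest.approx(1.0)

    def test_antisymmetry(self):
        cfg = NetworkConfig.pair("power", 1.0, [5.0, 10.0], 0.1, 0.7)
        traj = simulate_network(cfg, state0=(np.ones(2), np.array([0.3, 2.1])),
                                duration=20.0)
        psi_ij = normalized_phase(traj, 0, 1)
        psi_ji = normalized_phase(traj, 1, 0)
        assert np.array_equal(psi_ij, -psi_ji)


class TestSigmaDeviation:
    def test_desired_solution_gives_zero(self):
        theta, wi, wj = -1.8968, 5.0, 10.0
        assert sigma_deviation(theta / (wi * wj), theta, wi, wj) == pytest.approx(0.0)

    def test_zero_theta_identity(self):
        assert sigma_deviation(0.42, 0.0, 5.0, 10.0) == pytest.approx(0.42)

    def test_spurious_branch_value(self):
        psi = -0.038 + TWO_PI / 5.0
        sigma = sigma_deviation(psi, -1.8968, 5.0, 10.0)
        assert sigma == pytest.approx(TWO_PI / 5.0, abs=2.1e-3)


class TestDetectSteadyState:
    def test_constant_series(self):
        series = np.full(100, 3.7)
        assert detect_steady_state(series, dt=0.1, window=5.0) == pytest.approx(3.7)

    def test_drifting_series_rejected(self):
        series = np.linspace(0.0, 10.0, 100)
        assert detect_steady_state(series, dt=0.1, window=5.0) is None

    def test_exponential_convergence(self):
        t = np.arange(0, 100, 0.1)
        v, tau = 2.5, 1.0
        series = v + 3.0 * np.exp(-t / tau)
        out = detect_steady_state(series, dt=0.1, tol=1e-4, window=10.0)
        assert out == pytest.approx(v, abs=1e-3)

    def test_window_longer_than_series(self):
        with pytest.raises(ValueError):
            detect_steady_state(np.ones(10), dt=0.1, window=10.0)


class TestClusterSolutions:
    def test_two_groups(self):
        vals = np.array([0.0, 0.01, 1.25, 1.26, -0.01, np.nan])
        means, counts = cluster_solutions(vals, gap=0.05)
        assert len(means) == 2
        assert counts.tolist() == [3, 2]
        assert means[1] == pytest.approx(1.255)


class TestBasinScan:
    def _pair_cfg(self, A=0.2, theta=2.9644):
        return NetworkConfig.pair("power", 1.0, [5.0, 10.0], A, theta)

    def test_decoupled_scan_keeps_initial_sigma(self):
        cfg = self._pair_cfg(A=0.0)
        grid = np.arange(1.0, TWO_PI, 2.0)
        sol = basin_scan(cfg, [grid, grid], duration=20.0, pair=(0, 1))
        psi0 = sol.points[:, 0] / 5.0 - sol.points[:, 1] / 10.0
        assert np.allclose(sol.sigma, psi0 - 2.9644 / 50.0, atol=1e-9)

    def test_fig6b_nonzero_magnitude(self):
        cfg = self._pair_cfg()
        grid = np.arange(0.5, TWO_PI + 1e-9, 0.5)
        sol = basin_scan(cfg, [grid, grid], duration=200.0, pair=(0, 1))
        assert sol.n_unconverged == 0
        assert sol.dominant_nonzero_magnitude() == pytest.approx(1.257, abs=0.02)
        # all clusters lie on the {0, +-2*pi/w1} solution lattice
        for s in sol.solutions:
            assert min(abs(s), abs(abs(s) - TWO_PI / 5.0)) < 0.02

    def test_slice_mode_fixes_an_oscillator(self):
        cfg = self._pair_cfg()
        grid = np.arange(1.0, TWO_PI, 2.0)
        sol = basin_scan(cfg, [grid, grid], duration=50.0, pair=(0, 1),
                         fixed_phases={1: 1.5})
        assert np.all(sol.points[:, 1] == 1.5)

    def test_batch_matches_sequential(self):
        cfg = self._pair_cfg()
        grid = np.arange(1.0, TWO_PI, 2.5)
        pts = np.array([[a, b] for a in grid for b in grid])
        rec_p, rec_w = _simulate_batch(cfg, np.ones((len(pts), 2)), pts,
                                       duration=5.0, stride=10)
        for k, pt in enumerate(pts):
            p1, w1 = _simulate_batch(cfg, np.ones((1, 2)), pt[None, :],
                                     duration=5.0, stride=10)
            assert np.array_equal(p1[0], rec_p[k])
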