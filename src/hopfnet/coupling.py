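"""Real, complex and power coupling between oscillators.

Power coupling is the frequency-transforming lateral connection

    drive_i = sum_j A_ij * exp(i*theta_ij/w_j) * z_j^(w_i/w_j)

with the non-integer power defined on the unwrapped phase:
``z^(w_i/w_j) = r^(w_i/w_j) * exp(i*(w_i/w_j)*phi)``.  It stabilizes the
*normalized* phase difference ``psi_ij = phi_i/w_i - phi_j/w_j`` (units of
seconds) at the desired value ``theta_ij/(w_i*w_j)`` — plus a set of
spurious solutions reached from other initial conditions, which this module
maps with grid scans over initial phases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .core import DEFAULT_DT, OscillatorParams, OscillatorState, Trajectory

COUPLING_KINDS = {"none": _kernels.KIND_NONE,
                  "real": _kernels.KIND_REAL,
                  "complex": _kernels.KIND_COMPLEX,
                  "power": _kernels.KIND_POWER}


@dataclass
class PowerWeight:
    """Directed lateral connection feeding oscillator ``target`` from
    ``source``; realized as ``W_ij = A * exp(i*theta/w_j)`` for power
    coupling (for complex coupling ``theta`` is the weight angle itself, for
    real coupling the signed coefficient is ``A*cos(theta)``)."""

    source: int
    target: int
    A: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("weight magnitude must be non-negative")
        if self.source == self.target:
            raise ValueError("no self-coupling")


@dataclass
class NetworkConfig:
    """A network of supercritical Hopf oscillators plus its coupling.

    ``weights`` may be a list of :class:`PowerWeight` or a pair of dense
    (N, N) arrays ``(A, theta)``.  ``connectivity_mask`` (N, N boolean)
    zeroes masked-out pairs.  ``eps_force`` scales external forcing terms.
    """

    N: int
    coupling_kind: str = "power"
    params: Optional[List[OscillatorParams]] = None
    weights: object = None
    eps_force: float = 1.0
    dt: float = DEFAULT_DT
    connectivity_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.coupling_kind not in COUPLING_KINDS:
            raise ValueError(f"unknown coupling kind {self.coupling_kind!r}")
        if self.params is None:
            self.params = [OscillatorParams.supercritical() for _ in range(self.N)]
        if len(self.params) != self.N:
            raise ValueError("params length must equal N")

    @property
    def mu(self) -> np.ndarray:
        return np.array([p.mu for p in self.params])

    @property
    def omega(self) -> np.ndarray:
        return np.array([p.omega for p in self.params])

    def weight_matrices(self) -> Tuple[np.ndarray, np.ndarray]:
        """Dense (A, theta) matrices with zero diagonal and mask applied."""
        A = np.zeros((self.N, self.N))
        th = np.zeros((self.N, self.N))
        if self.weights is None:
            pass
        elif isinstance(self.weights, (list, tuple)) and (
                len(self.weights) == 0 or isinstance(self.weights[0], PowerWeight)):
            for w in self.weights:
                A[w.target, w.source] = w.A
                th[w.target, w.source] = w.theta
        else:
            A, th = (np.array(self.weights[0], dtype=float),
                     np.array(self.weights[1], dtype=float))
            A = A.copy()
            th = th.copy()
        np.fill_diagonal(A, 0.0)
        if self.connectivity_mask is not None:
            A = np.where(self.connectivity_mask, A, 0.0)
            np.fill_diagonal(A, 0.0)
        return A, th

    @classmethod
    def pair(cls, kind: str, mu: float, omegas: Sequence[float],
             A: float, theta: float, hermitian: bool = True,
             dt: float = DEFAULT_DT, eps_force: float = 1.0) -> "NetworkConfig":
        """Bidirectionally coupled pair with theta_12 = theta and, under the
        Hermitian-style constraint, theta_21 = -theta."""
        w12 = PowerWeight(source=1, target=0, A=A, theta=theta)
        w21 = PowerWeight(source=0, target=1, A=A,
                          theta=-theta if hermitian else theta)
        params = [OscillatorParams.supercritical(mu, w) for w in omegas]
        return cls(N=2, coupling_kind=kind, params=params,
                   weights=[w12, w21], dt=dt, eps_force=eps_force)


def coupling_drive(states: Sequence[OscillatorState],
                   omegas: Sequence[float],
                   weights: Tuple[np.ndarray, np.ndarray],
                   kind: str,
                   target: int) -> complex:
    """Summed lateral input to oscillator ``target`` for the given kind."""
    A, th = weights
    omegas = np.asarray(omegas, dtype=float)
    if kind == "power" and np.any(omegas <= 0):
        raise ValueError("power coupling requires strictly positive omegas")
    i = target
    drive = 0.0 + 0.0j
    for j, s in enumerate(states):
        if j == i or A[i, j] == 0.0:
            continue
        if kind == "real":
            drive += A[i, j] * np.cos(th[i, j]) * (s.r * np.cos(s.phi))
        elif kind == "complex":
            drive += A[i, j] * np.exp(1j * th[i, j]) * s.z
        elif kind == "power":
            ex = omegas[i] / omegas[j]
            drive += (A[i, j] * np.exp(1j * th[i, j] / omegas[j])
                      * s.r ** ex * np.exp(1j * ex * s.phi))
        else:
            raise ValueError(f"unknown coupling kind {kind!r}")
    return complex(drive)


def _forcing_arrays(N, forcings):
    fk = np.zeros(N, dtype=np.int64)
    I0 = np.zeros(N)
    wf = np.zeros(N)
    pf = np.zeros(N)
    if forcings is not None:
        kinds = {"none": 0, "real-sinusoid": 1, "complex-sinusoid": 2}
        for i, f in enumerate(forcings):
            if f is None:
                continue
            fk[i] = kinds[f.kind]
            I0[i] = f.I0
            wf[i] = f.omega0
            pf[i] = f.phase_offset
    return fk, I0, wf, pf


def _as_batch(state0, N):
    """Normalize initial conditions to (B, N) r and phi arrays."""
    if state0 is None:
        r0 = np.ones((1, N))
        p0 = np.zeros((1, N))
    elif isinstance(state0, (list, tuple)) and isinstance(state0[0], OscillatorState):
        r0 = np.array([[s.r for s in state0]])
        p0 = np.array([[s.phi for s in state0]])
    else:
        r0, p0 = state0
        r0 = np.atleast_2d(np.asarray(r0, dtype=float))
        p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    return r0, p0


def simulate_network(config: NetworkConfig,
                     state0=None,
                     forcings=None,
                     duration: float = 100.0,
                     stride: int = 10,
                     learn_theta: bool = False,
                     learn_omega: bool = False,
                     learn_A: bool = False,
                     tau_w: float = 1e3,
                     record_theta: bool = False) -> Trajectory:
    """Polar-form Euler trajectory of the whole network.

    ``state0`` may be a list of :class:`OscillatorState` or an ``(r0, phi0)``
    array pair.  Learning flags switch on the Hebbian weight-angle update and
    the frequency-adaptation update (see :mod:`hopfnet.plasticity`).
    """
    kind = COUPLING_KINDS[config.coupling_kind]
    if kind == _kernels.KIND_POWER and np.any(config.omega <= 0):
        raise ValueError("power coupling requires strictly positive omegas")
    A, th = config.weight_matrices()
    r0, p0 = _as_batch(state0, config.N)
    om0 = np.broadcast_to(config.omega, r0.shape).astype(float).copy()
    fk, I0, wf, pf = _forcing_arrays(config.N, forcings)
    n_steps = int(round(duration / config.dt))
    rec_r, rec_p, rec_w, rec_th, rec_A = _kernels.hopf_network(
        config.mu, om0, r0, p0,
        np.broadcast_to(A, (r0.shape[0],) + A.shape).copy(),
        np.broadcast_to(th, (r0.shape[0],) + th.shape).copy(),
        kind, fk, I0, wf, pf, config.eps_force,
        learn_theta, learn_A, learn_omega, tau_w,
        config.dt, n_steps, stride, record_theta)
    t = _kernels.record_times(n_steps, stride, config.dt)
    return Trajectory(t=t, r=rec_r[0], phi=rec_p[0], omega=rec_w[0],
                      theta=rec_th[0] if record_theta else rec_th[0, -1],
                      A=rec_A[0] if record_theta else rec_A[0, -1],
                      dt=config.dt * stride)


def simulate_kuramoto(config: NetworkConfig,
                      kind: str = "power",
                      forcings=None,
                      duration: float = 100.0,
                      phi0=None,
                      stride: int = 10) -> Trajectory:
    """Phase-only variant: real Kuramoto coupling ``K*sin(phi_j - phi_i)`` or
    its power-coupling analogue."""
    if kind not in ("real", "power"):
        raise ValueError("kuramoto kind must be 'real' or 'power'")
    if kind == "power" and np.any(config.omega <= 0):
        raise ValueError("power coupling requires strictly positive omegas")
    A, th = config.weight_matrices()
    if phi0 is None:
        phi0 = np.zeros((1, config.N))
    phi0 = np.atleast_2d(np.asarray(phi0, dtype=float))
    fk, I0, wf, pf = _forcing_arrays(config.N, forcings)
    n_steps = int(round(duration / config.dt))
    rec_p = _kernels.kuramoto_network(
        config.omega, phi0, A, th, COUPLING_KINDS[kind],
        fk, I0, wf, pf, config.dt, n_steps, stride)
    t = _kernels.record_times(n_steps, stride, config.dt)
    om = np.broadcast_to(config.omega, rec_p[0].shape).copy()
    return Trajectory(t=t, r=np.ones_like(rec_p[0]), phi=rec_p[0], omega=om,
                      dt=config.dt * stride)


def normalized_phase(traj: Trajectory, i: int, j: int) -> np.ndarray:
    """Normalized phase difference psi_ij(t) = phi_i/w_i - phi_j/w_j, using
    the current natural frequencies (seconds)."""
    if traj.omega is None:
        raise ValueError("trajectory lacks an omega series")
    wi = traj.omega[:, i]
    wj = traj.omega[:, j]
    if np.any(wi == 0) or np.any(wj == 0):
        raise ValueError("normalized phase undefined at omega == 0")
    return traj.phi[:, i] / wi - traj.phi[:, j] / wj


def sigma_deviation(psi_ss, theta_ij: float, omega_i: float, omega_j: float):
    """Deviation sigma_ij = psi_ij - theta_ij/(w_i*w_j); zero at the desired
    solution, nonzero at spurious attractors."""
    if omega_i <= 0 or omega_j <= 0:
        raise ValueError("omegas must be positive")
    return psi_ss - theta_ij / (omega_i * omega_j)


def detect_steady_state(series: np.ndarray, dt: float,
                        tol: float = 1e-4, window: float = 10.0):
    """Trailing-window mean of ``series`` if its finite-difference rate stays
    below ``tol`` throughout the window; ``None`` otherwise."""
    series = np.asarray(series, dtype=float)
    n = int(round(window / dt))
    if n < 2:
        n = 2
    if n > len(series):
        raise ValueError("window longer than the series")
    tail = series[-n:]
    rate = np.max(np.abs(np.diff(tail))) / dt
    if rate < tol:
        return float(np.mean(tail))
    return None


def cluster_solutions(values: np.ndarray, gap: float = 0.05):
    """1-D agglomerative merge: sort, split where consecutive gaps exceed
    ``gap``; returns (cluster means, cluster sizes)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.array([]), np.array([], dtype=int)
    order = np.sort(values)
    splits = np.where(np.diff(order) > gap)[0] + 1
    groups = np.split(order, splits)
    means = np.array([g.mean() for g in groups])
    counts = np.array([len(g) for g in groups])
    return means, counts


@dataclass
class SolutionMap:
    """Result of a basin scan: one steady sigma_ij value per grid point
    (NaN where no steady state was reached) plus the clustered solution
    set."""

    points: np.ndarray          # (P, N) initial phases
    sigma: np.ndarray           # (P,) steady sigma values, NaN if unconverged
    pair: Tuple[int, int]
    solutions: np.ndarray = field(default=None)
    counts: np.ndarray = field(default=None)
    cluster_gap: float = 0.05

    def cluster(self, gap: Optional[float] = None):
        gap = self.cluster_gap if gap is None else gap
        self.solutions, self.counts = cluster_solutions(self.sigma, gap)
        return self.solutions, self.counts

    @property
    def n_unconverged(self) -> int:
        return int(np.sum(~np.isfinite(self.sigma)))

    def dominant_nonzero_magnitude(self, zero_tol: float = 0.02):
        """|mean| of the most populated cluster away from zero (or None)."""
        if self.solutions is None:
            self.cluster()
        keep = np.abs(self.solutions) > zero_tol
        if not np.any(keep):
            return None
        sols = self.solutions[keep]
        cnts = self.counts[keep]
        return float(abs(sols[np.argmax(cnts)]))

    def dominant_positive_solution(self, zero_tol: float = 0.02):
        """Most populated cluster mean above ``zero_tol`` (or None)."""
        if self.solutions is None:
            self.cluster()
        keep = self.solutions > zero_tol
        if not np.any(keep):
            return None
        sols = self.solutions[keep]
        cnts = self.counts[keep]
        return float(sols[np.argmax(cnts)])


def basin_scan(config: NetworkConfig,
               phase_grid: Sequence[np.ndarray],
               duration: float,
               pair: Tuple[int, int],
               stride: int = 20,
               steady_tol: float = 1e-4,
               steady_window: Optional[float] = None,
               cluster_gap: float = 0.05,
               fixed_phases: Optional[dict] = None) -> SolutionMap:
    """Scan steady sigma_ij over a grid of initial phases.

    ``phase_grid`` gives the candidate initial-phase values per oscillator
    (use ``fixed_phases={k: value}`` to hold oscillator k at one value — the
    slice mode).  All grid points are integrated as one vectorized batch;
    non-converged points are recorded as NaN, never dropped.
    """
    i, j = pair
    grids = [np.asarray(g, dtype=float) for g in phase_grid]
    if fixed_phases:
        for k, v in fixed_phases.items():
            grids[k] = np.array([float(v)])
    for g in grids:
        if len(g) > 1 and np.any(np.diff(np.sort(g)) <= 0):
            raise ValueError("grid spacing must be positive")
    points = np.array(list(itertools.product(*grids)))
    B = points.shape[0]
    r0 = np.ones((B, config.N))
    traj_batch = _simulate_batch(config, r0, points, duration, stride)
    rec_p, rec_w = traj_batch
    dt_rec = config.dt * stride
    if steady_window is None:
        steady_window = 0.1 * duration
    A, th = config.weight_matrices()
    wi = config.omega[i]
    wj = config.omega[j]
    sigma = np.full(B, np.nan)
    n_tail = max(2, int(round(steady_window / dt_rec)))
    psi = rec_p[:, :, i] / rec_w[:, :, i] - rec_p[:, :, j] / rec_w[:, :, j]
    tails = psi[:, -n_tail:]
    rates = np.max(np.abs(np.diff(tails, axis=1)), axis=1) / dt_rec
    means = np.mean(tails, axis=1)
    ok = rates < steady_tol
    sigma[ok] = means[ok] - th[i, j] / (wi * wj)
    sol = SolutionMap(points=points, sigma=sigma, pair=pair, cluster_gap=cluster_gap)
    sol.cluster()
    return sol


def _simulate_batch(config, r0, p0, duration, stride):
    """Vectorized batch run; returns recorded (phi, omega) arrays."""
    kind = COUPLING_KINDS[config.coupling_kind]
    A, th = config.weight_matrices()
    B = r0.shape[0]
    om0 = np.broadcast_to(config.omega, r0.shape).astype(float).copy()
    fk, I0, wf, pf = _forcing_arrays(config.N, None)
    n_steps = int(round(duration / config.dt))
    _, rec_p, rec_w, _, _ = _kernels.hopf_network(
        config.mu, om0, np.ascontiguousarray(r0), np.ascontiguousarray(p0),
        np.broadcast_to(A, (B,) + A.shape).copy(),
        np.broadcast_to(th, (B,) + th.shape).copy(),
        kind, fk, I0, wf, pf, config.eps_force,
        False, False, False, 1.0,
        config.dt, n_steps, stride, False)
    return rec_p, rec_w
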