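"""Fourier-like decomposition by an error-driven oscillator reservoir.

A bank of N adaptive-frequency Hopf oscillators is driven by the shared
reconstruction error ``e(t) = D(t) - P(t)``.  In real mode the readout is
``P(t) = sum_i alpha_i * cos(phi_i)``; in complex mode ``P = sum_i
alpha_i * z_i``.  The natural frequencies migrate onto the spectral
components of the teaching signal, the real readout weights learn the
component amplitudes, and the lateral power-coupling angles learn the
pairwise normalized phase offsets ``phi_i*w_j - phi_j*w_i``.  After
training the reservoir regenerates the signal autonomously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .core import DEFAULT_DT, Trajectory
from .plasticity import LearningConfig

log = logging.getLogger(__name__)


@dataclass
class TeachingSignal:
    """Uniformly sampled teaching series (real or complex, 1 or M channels)."""

    samples: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("teaching signal contains non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] * self.dt

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.samples)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) * self.dt


@dataclass
class TrainedReservoir:
    """Learned reservoir parameters: natural frequencies, real readout
    weights, lateral power weights, and the regeneration init convention
    (all oscillators at z = 1)."""

    omegas: np.ndarray
    alphas: np.ndarray
    A: np.ndarray
    theta: np.ndarray
    mode: str = "real"
    mu: float = 1.0
    dt: float = DEFAULT_DT
    init_r: float = 1.0
    init_phi: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.alphas = np.asarray(self.alphas, dtype=float)
        if np.any(self.omegas <= 0):
            raise ValueError("reservoir omegas must be positive")

    @property
    def N(self) -> int:
        return len(self.omegas)


def default_omega_init(N: int, band: Tuple[float, float] = (3.0, 14.0)) -> np.ndarray:
    """Even spread of initial natural frequencies over ``band`` (rad/s)."""
    lo, hi = band
    return np.linspace(lo, hi, N)


def train_reservoir(signal: TeachingSignal,
                    N: int,
                    learning: Optional[LearningConfig] = None,
                    mode: str = "real",
                    epochs: int = 1,
                    omega_init=None,
                    A_lateral: float = 1e-5,
                    connectivity_mask: Optional[np.ndarray] = None,
                    eps: float = 0.5,
                    mu: float = 1.0,
                    duration: Optional[float] = None,
                    theta_init: Optional[np.ndarray] = None,
                    alpha_init: Optional[np.ndarray] = None,
                    r_init: Optional[np.ndarray] = None,
                    phi_init: Optional[np.ndarray] = None,
                    stride: Optional[int] = None,
                    learn_theta: bool = True,
                    record_theta: bool = False,
                    readout_with_r: bool = False,
                    exact_synthesis: Optional[bool] = None,
                    theta_consolidation: float = 10.0
                    ) -> Tuple[TrainedReservoir, Trajectory]:
    """Train the reservoir on ``signal``.

    Oscillator state carries over across epochs while the teaching signal
    restarts each epoch.  ``duration`` (seconds) overrides
    ``epochs * signal.duration`` for long continuous presentations of a
    periodic signal; in that case, when the signal carries its component
    list, the teaching value is synthesized exactly at every step instead of
    wrapping the sampled chunk (a chunk whose length is not a multiple of
    the fundamental period would otherwise inject phase jumps at each
    restart).  ``exact_synthesis`` overrides the automatic choice.
    Defaults: r(0)=1, phi(0)=0, alpha(0)=0, and an even spread of initial
    frequencies.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if mode not in ("real", "complex"):
        raise ValueError("mode must be 'real' or 'complex'")
    if mode == "real" and signal.is_complex:
        raise ValueError("real mode requires a real teaching signal")
    learning = learning or LearningConfig(tau_w=1e4)
    dt = signal.dt
    sig = signal.samples.astype(complex if mode == "complex" else float)
    sig_len = len(sig)
    if duration is None:
        n_steps = epochs * sig_len
    else:
        n_steps = int(round(duration / dt))
    if omega_init is None:
        omega_init = default_omega_init(N)
    omega_init = np.asarray(omega_init, dtype=float)
    A = np.full((N, N), A_lateral)
    np.fill_diagonal(A, 0.0)
    if connectivity_mask is not None:
        A = np.where(connectivity_mask, A, 0.0)
        np.fill_diagonal(A, 0.0)
    th0 = np.zeros((N, N)) if theta_init is None else np.asarray(theta_init, dtype=float).copy()
    a0 = np.zeros(N) if alpha_init is None else np.asarray(alpha_init, dtype=float).copy()
    if stride is None:
        stride = max(1, n_steps // 2000)
    is_complex = mode == "complex"
    D_re = np.ascontiguousarray(np.real(sig), dtype=np.float64)
    D_im = np.ascontiguousarray(np.imag(sig), dtype=np.float64)
    comps = signal.meta.get("components")
    if exact_synthesis is None:
        exact_synthesis = duration is not None and comps is not None
    if exact_synthesis and not comps:
        raise ValueError("exact synthesis requires the signal's component list")
    if exact_synthesis:
        comp_a = np.array([c[0] for c in comps], dtype=np.float64)
        comp_w = np.array([c[1] for c in comps], dtype=np.float64)
        comp_p = np.array([c[2] for c in comps], dtype=np.float64)
    else:
        comp_a = np.empty(0)
        comp_w = np.empty(0)
        comp_p = np.empty(0)
    r0 = np.ones(N) if r_init is None else np.asarray(r_init, dtype=float).copy()
    p0 = np.zeros(N) if phi_init is None else np.asarray(phi_init, dtype=float).copy()
    rec_r, rec_p, rec_w, rec_a, rec_P, rec_e, rec_th, epoch_err = _kernels.reservoir_train(
        is_complex, D_re, D_im,
        np.full(N, mu), omega_init.copy(), r0, p0, a0,
        A, th0, eps, learning.eta_omega, learning.eta_alpha, learning.tau_w,
        learn_theta and np.any(A > 0),
        dt, n_steps, sig_len, stride, record_theta, readout_with_r,
        comp_a, comp_w, comp_p, 0.0, 0)
    theta_final = rec_th[-1].copy()
    if theta_consolidation > 0 and learn_theta and np.any(A > 0):
        n_cons = int(round(theta_consolidation / dt))
        # reduce phases to their principal values at the checkpoint so the
        # consolidated angles land on the principal representative (whole
        # phase turns accumulated during adaptation would otherwise shift
        # the realized coupling by exp(-2i*pi*n*w_i/w_j) and can strand the
        # z(0)=1 regeneration in a spurious basin)
        p_cons = np.mod(rec_p[-1], 2.0 * np.pi)
        out = _kernels.reservoir_train(
            is_complex, D_re, D_im,
            np.full(N, mu), rec_w[-1].copy(), rec_r[-1].copy(),
            p_cons, rec_a[-1].copy(),
            A, theta_final, eps, 0.0, 0.0, learning.tau_w,
            True, dt, n_cons, sig_len, max(1, n_cons), False,
            readout_with_r, comp_a, comp_w, comp_p,
            n_steps * dt, n_steps % sig_len)
        theta_final = out[6][-1].copy()
    t = _kernels.record_times(n_steps, stride, dt)
    output = rec_P[:, 0] + 1j * rec_P[:, 1] if is_complex else rec_P[:, 0]
    error = rec_e[:, 0] + 1j * rec_e[:, 1] if is_complex else rec_e[:, 0]
    traj = Trajectory(t=t, r=rec_r, phi=rec_p, omega=rec_w, alpha=rec_a,
                      theta=rec_th if record_theta else rec_th[-1],
                      output=output, error=error, epoch_error=epoch_err,
                      dt=dt * stride)
    trained = TrainedReservoir(omegas=rec_w[-1].copy(), alphas=rec_a[-1].copy(),
                               A=A, theta=theta_final, mode=mode, mu=mu, dt=dt)
    _flag_collisions(trained)
    return trained, traj


def _flag_collisions(trained: TrainedReservoir, gap: float = 0.1) -> None:
    """Report (never merge) oscillators whose learned frequencies collide."""
    w = np.sort(trained.omegas)
    close = np.where(np.diff(w) < gap)[0]
    if close.size:
        pairs = [(float(w[k]), float(w[k + 1])) for k in close]
        trained.meta["degenerate_frequencies"] = pairs
        log.warning("%d learned frequency pairs closer than %g rad/s "
                    "(first: %.3f/%.3f)", len(pairs), gap, *pairs[0])


def run_autonomous(trained: TrainedReservoir, duration: float,
                   A_retrieve: Optional[float] = None,
                   stride: int = 1) -> Trajectory:
    """Free run of the trained reservoir from z_i(0) = 1 (no error feedback,
    no external input); lateral weights active at ``A_retrieve``."""
    N = trained.N
    A = trained.A.copy()
    if A_retrieve is not None:
        A = np.where(A > 0, A_retrieve, 0.0)
    r0 = np.full((1, N), trained.init_r)
    p0 = np.full((1, N), trained.init_phi)
    fk = np.zeros(N, dtype=np.int64)
    zeros = np.zeros(N)
    n_steps = int(round(duration / trained.dt))
    rec_r, rec_p, rec_w, _, _ = _kernels.hopf_network(
        np.full(N, trained.mu), trained.omegas[None, :].copy(), r0, p0,
        A[None, :, :].copy(), trained.theta[None, :, :].copy(),
        _kernels.KIND_POWER, fk, zeros, zeros, zeros, 1.0,
        False, False, False, 1.0,
        trained.dt, n_steps, stride, False)
    t = _kernels.record_times(n_steps, stride, trained.dt)
    return Trajectory(t=t, r=rec_r[0], phi=rec_p[0], omega=rec_w[0],
                      dt=trained.dt * stride)


def readout(trained: TrainedReservoir, traj: Trajectory) -> np.ndarray:
    """Apply the trained readout to a trajectory (real or complex form)."""
    if trained.mode == "complex":
        return (trained.alphas * traj.r * np.exp(1j * traj.phi)).sum(axis=1)
    return (trained.alphas * np.cos(traj.phi)).sum(axis=1)


def regenerate(trained: TrainedReservoir, duration: float,
               A_retrieve: float = 0.1) -> Tuple[np.ndarray, np.ndarray]:
    """Autonomous regeneration: returns (t, P(t)) from the free run."""
    traj = run_autonomous(trained, duration, A_retrieve=A_retrieve)
    return traj.t, readout(trained, traj)


def regeneration_error(trained: TrainedReservoir, signal: TeachingSignal,
                       duration: float = 10.0, settle: float = 20.0,
                       A_retrieve: float = 0.1, align: bool = True) -> float:
    """Relative mean-squared error of the regenerated output against the
    teaching signal over a ``duration`` window after ``settle`` seconds.

    An autonomous oscillator network is defined only up to a common time
    translation (the coupled dynamics pin all pairwise normalized phase
    differences but leave one neutral common mode), so by default the error
    is minimized over a time shift of the teaching signal; ``align=False``
    compares at the nominal origin.
    """
    t, P = regenerate(trained, settle + duration, A_retrieve=A_retrieve)
    n_keep = int(round(duration / trained.dt))
    P_tail = np.real(P[-n_keep:]) if trained.mode == "real" else P[-n_keep:]
    t_tail = t[-n_keep:]
    comps = signal.meta.get("components")
    denom = float(np.mean(np.abs(signal.samples) ** 2))

    def mse_at(shift: float) -> float:
        D = _eval_signal(signal, t_tail + shift)
        if trained.mode == "real":
            D = np.real(D)
        return float(np.mean(np.abs(D - P_tail) ** 2)) / denom

    if not align:
        return mse_at(0.0)
    # coarse-to-fine scan over one fundamental-ish period of shifts
    if comps:
        w_min = min(c[1] for c in comps)
    else:
        w_min = float(np.min(trained.omegas))
    span = 2 * np.pi / w_min
    shifts = np.linspace(-span, span, 241)
    coarse = np.array([mse_at(s) for s in shifts])
    s0 = shifts[np.argmin(coarse)]
    fine = np.linspace(s0 - span / 120, s0 + span / 120, 81)
    vals = np.array([mse_at(s) for s in fine])
    return float(np.min(vals))


def _eval_signal(signal: TeachingSignal, t: np.ndarray) -> np.ndarray:
    """Evaluate the signal at arbitrary times: exactly from its component
    list when available, otherwise by interpolation of the samples."""
    comps = signal.meta.get("components")
    if comps:
        out = np.zeros_like(t, dtype=complex)
        for a, w, ph in comps:
            if signal.meta.get("domain") == "complex":
                out = out + a * np.exp(1j * (w * t + ph))
            else:
                out = out + a * np.cos(w * t + ph)
        return out
    base_t = signal.t
    tt = np.mod(t, base_t[-1] + signal.dt)
    if signal.is_complex:
        return (np.interp(tt, base_t, signal.samples.real)
                + 1j * np.interp(tt, base_t, signal.samples.imag))
    return np.interp(tt, base_t, signal.samples)


def spectrum_report(trained: TrainedReservoir, degenerate_gap: float = 0.1):
    """Sorted-by-frequency table of (omega, alpha) plus pairwise normalized
    phase offsets theta_ij/(w_i*w_j); degenerate frequencies are flagged."""
    import pandas as pd

    order = np.argsort(trained.omegas)
    w = trained.omegas[order]
    a = trained.alphas[order]
    rows = {"omega": w, "alpha": a}
    df = pd.DataFrame(rows)
    offsets = {}
    for ii in range(trained.N):
        for jj in range(trained.N):
            if ii == jj:
                continue
            i, j = order[ii], order[jj]
            offsets[(ii, jj)] = trained.theta[i, j] / (trained.omegas[i] * trained.omegas[j])
    df.attrs["normalized_offsets"] = offsets
    df.attrs["degenerate"] = [(float(w[k]), float(w[k + 1]))
                              for k in np.where(np.diff(w) < degenerate_gap)[0]]
    return df
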