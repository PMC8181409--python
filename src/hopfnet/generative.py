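"""Two-phase generative model for multichannel signals.

Phase 1 encodes the spectrum of one reference channel into a reservoir of
adaptive-frequency Hopf oscillators (banded lateral power coupling, the
finite teaching signal presented repeatedly over epochs).  Phase 2 freezes
the reservoir, runs it autonomously from z_i(0) = 1, and fits complex
feed-forward readout weights ``W^f_ij = K_ij * exp(i*zeta_ij)`` so that

    Y_p_i(t) = Re( sum_j W^f_ij * exp(i*phi_j(t)) )

reconstructs M target channels.  The batch updates descend the summed
squared error; starting every reconstruction run from z_i(0) = 1 is what
makes the frozen phase trajectories reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .core import DEFAULT_DT
from .plasticity import LearningConfig
from .reservoir import TeachingSignal, TrainedReservoir, run_autonomous, train_reservoir

TWO_PI = 2.0 * np.pi


@dataclass
class ReadoutWeights:
    """Complex feed-forward readout: magnitudes K (M, N) >= 0 and angles
    zeta (M, N)."""

    K: np.ndarray
    zeta: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.K.shape != self.zeta.shape:
            raise ValueError("K and zeta must share a shape")
        if not (np.all(np.isfinite(self.K)) and np.all(np.isfinite(self.zeta))):
            raise ValueError("readout weights must be finite")

    @property
    def W(self) -> np.ndarray:
        return self.K * np.exp(1j * self.zeta)


@dataclass
class MultichannelTarget:
    """M real target channels on a uniform time grid."""

    Y: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.ndim != 2:
            raise ValueError("Y must be (n, M)")

    @property
    def M(self) -> int:
        return self.Y.shape[1]

    @property
    def duration(self) -> float:
        return self.Y.shape[0] * self.dt


def phase1_encode(signal: TeachingSignal,
                  N: int,
                  band: Tuple[float, float],
                  bandwidth: int = 5,
                  epochs: int = 30,
                  learning: Optional[LearningConfig] = None,
                  seed: Optional[int] = None,
                  A_lateral: float = 0.1,
                  eps: float = 0.5) -> TrainedReservoir:
    """Phase 1: encode the reference channel's spectrum.

    Initial natural frequencies are sampled uniformly on ``band`` (Hz),
    sorted ascending, and converted to rad/s; the lateral mask keeps only
    |i - j| < ``bandwidth`` so that, after sorting, only oscillators with
    nearby frequencies interact.  ``bandwidth = 0`` disables lateral
    coupling entirely (frequencies still adapt).
    """
    if band[0] >= band[1]:
        raise ValueError("degenerate band")
    if signal.is_complex:
        raise ValueError("phase 1 trains on a real reference channel")
    rng = np.random.default_rng(seed)
    omega0 = np.sort(rng.uniform(band[0], band[1], N)) * TWO_PI
    omega0 = np.maximum(omega0, 1e-2)  # keep power coupling well-defined
    idx = np.arange(N)
    mask = np.abs(idx[:, None] - idx[None, :]) < bandwidth
    np.fill_diagonal(mask, False)
    learning = learning or LearningConfig(tau_w=1e4, eta_omega=0.1, eta_alpha=1e-4)
    trained, _ = train_reservoir(signal, N, learning=learning, mode="real",
                                 epochs=epochs, omega_init=omega0,
                                 A_lateral=A_lateral, connectivity_mask=mask,
                                 eps=eps)
    trained.meta["band_hz"] = band
    trained.meta["seed"] = seed
    return trained


def frozen_phases(reservoir: TrainedReservoir, duration: float) -> np.ndarray:
    """Phase trajectories phi_j(t) of one autonomous run from z_i(0) = 1,
    at the reservoir's dt (shape (T, N)); reused across batch epochs."""
    traj = run_autonomous(reservoir, duration, A_retrieve=None, stride=1)
    n = int(round(duration / reservoir.dt))
    return traj.phi[:n]


def predict_from_phases(phis: np.ndarray, readout: ReadoutWeights) -> np.ndarray:
    """Y_p(t) (T, M) = Re(sum_j K_ij e^{i zeta_ij} e^{i phi_j(t)})."""
    C = np.cos(phis)
    S = np.sin(phis)
    Kc = readout.K * np.cos(readout.zeta)
    Ks = readout.K * np.sin(readout.zeta)
    return C @ Kc.T - S @ Ks.T


def phase2_fit(reservoir: TrainedReservoir,
               targets: MultichannelTarget,
               eta_K: float = 3e-5,
               eta_zeta: float = 1e-6,
               epochs: int = 10000,
               init: Optional[ReadoutWeights] = None,
               seed: Optional[int] = None,
               return_phases: bool = False):
    """Phase 2: batch gradient fit of the complex readout.

    One frozen autonomous run provides phi_j(t); each epoch applies one
    batch update

        dK_ij    =  eta_K    * sum_t e_i(t) * cos(phi_j + zeta_ij)
        dzeta_ij = -eta_zeta * sum_t e_i(t) * K_ij * sin(phi_j + zeta_ij)

    with e = Y_d - Y_p, i.e. gradient *descent* on (1/2)*sum e^2.  K is kept
    non-negative by the (K, zeta) -> (-K, zeta+pi) symmetry.
    """
    if eta_K <= 0 or eta_zeta <= 0:
        raise ValueError("learning rates must be positive")
    if abs(targets.dt - reservoir.dt) > 1e-12:
        raise ValueError("target dt must match the reservoir dt")
    phis = frozen_phases(reservoir, targets.duration)
    T = min(len(phis), targets.Y.shape[0])
    phis = phis[:T]
    Yd = targets.Y[:T]
    M, N = targets.M, reservoir.N
    if init is None:
        if seed is None:
            K = np.zeros((M, N))
            zeta = np.zeros((M, N))
        else:
            rng = np.random.default_rng(seed)
            K = rng.uniform(0.0, 0.1, (M, N))
            zeta = rng.uniform(0.0, TWO_PI, (M, N))
    else:
        K = init.K.copy()
        zeta = init.zeta.copy()
    C = np.cos(phis)
    S = np.sin(phis)
    for _ in range(epochs):
        cz = np.cos(zeta)
        sz = np.sin(zeta)
        Yp = C @ (K * cz).T - S @ (K * sz).T
        E = Yd - Yp                     # (T, M)
        EC = E.T @ C                    # (M, N)
        ES = E.T @ S
        dK = eta_K * (EC * cz - ES * sz)
        dz = -eta_zeta * K * (ES * cz + EC * sz)
        K = K + dK
        zeta = zeta + dz
        neg = K < 0
        if np.any(neg):
            K = np.where(neg, -K, K)
            zeta = np.where(neg, zeta + np.pi, zeta)
    fitted = ReadoutWeights(K=K, zeta=zeta)
    if return_phases:
        return fitted, phis
    return fitted


def reconstruct(reservoir: TrainedReservoir,
                readout: ReadoutWeights,
                duration: float) -> Tuple[np.ndarray, np.ndarray]:
    """Autonomous reconstruction: (t, Y_p (T, M)) from z_i(0) = 1."""
    phis = frozen_phases(reservoir, duration)
    t = np.arange(len(phis)) * reservoir.dt
    return t, predict_from_phases(phis, readout)


def reconstruction_error(reservoir: TrainedReservoir,
                         readout: ReadoutWeights,
                         targets: MultichannelTarget) -> np.ndarray:
    """Per-channel relative MSE of the reconstruction against the targets."""
    _, Yp = reconstruct(reservoir, readout, targets.duration)
    T = min(len(Yp), targets.Y.shape[0])
    err = targets.Y[:T] - Yp[:T]
    return np.mean(err ** 2, axis=0) / np.mean(targets.Y[:T] ** 2, axis=0)
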