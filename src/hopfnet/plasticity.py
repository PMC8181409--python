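"""Hebb-like learning of complex and power-coupling weight angles.

The complex-coupling rule relaxes the weight toward ``z_1 * conj(z_2)``:

    tau_W * dA/dt     = -A + r1*r2*cos(phi1 - phi2 - theta)
    tau_W * dtheta/dt = (r1*r2/A) * sin(phi1 - phi2 - theta)

and the power-coupling analogue relaxes ``W_ij`` toward
``z_i * conj(z_j)^(w_i/w_j)``:

    tau_W * dtheta_ij/dt = w_j * (r_i * r_j^(w_i/w_j) / A_ij)
                           * sin(w_i*(phi_i/w_i - phi_j/w_j - theta_ij/(w_i*w_j)))

By default the magnitude is frozen (dA = 0) and only the angle learns; the
angle then encodes the observed (normalized) phase relationship.  Because
the realized weight depends on theta only through ``exp(i*theta/w_j)``,
learned angles are compared modulo ``2*pi*w_j`` (modulo ``2*pi`` for complex
coupling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import OscillatorState, Trajectory
from .coupling import NetworkConfig, PowerWeight, simulate_network

log = logging.getLogger(__name__)


@dataclass
class LearningConfig:
    """Time constant and rates of the learning dynamics."""

    tau_w: float = 1e3
    eta_omega: float = 0.1
    eta_alpha: float = 1e-4
    freeze_magnitude: bool = True

    def __post_init__(self) -> None:
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")


def hebb_complex_step(W: Tuple[float, float], z1: complex, z2: complex,
                      tau_w: float, freeze_magnitude: bool = True
                      ) -> Tuple[float, float]:
    """Polar-form increments (dA/dt, dtheta/dt) of the complex-coupling rule."""
    A, theta = W
    if A <= 0:
        raise ValueError("singular update: theta dynamics divide by A")
    r1, p1 = abs(z1), np.angle(z1)
    r2, p2 = abs(z2), np.angle(z2)
    dA = 0.0 if freeze_magnitude else (-A + r1 * r2 * np.cos(p1 - p2 - theta)) / tau_w
    dth = r1 * r2 * np.sin(p1 - p2 - theta) / (A * tau_w)
    return dA, dth


def hebb_power_step(weight: PowerWeight,
                    state_i: OscillatorState, state_j: OscillatorState,
                    omega_i: float, omega_j: float,
                    tau_w: float, freeze_magnitude: bool = True
                    ) -> Tuple[float, float]:
    """Polar-form increments of the power-coupling rule (unwrapped phases)."""
    if omega_i <= 0 or omega_j <= 0:
        raise ValueError("power coupling requires positive omegas")
    if weight.A <= 0:
        raise ValueError("singular update: theta dynamics divide by A")
    amp = state_i.r * state_j.r ** (omega_i / omega_j)
    arg = omega_i * (state_i.phi / omega_i - state_j.phi / omega_j
                     - weight.theta / (omega_i * omega_j))
    dA = 0.0 if freeze_magnitude else (-weight.A + amp * np.cos(arg)) / tau_w
    dth = omega_j * amp * np.sin(arg) / (weight.A * tau_w)
    return dA, dth


def simulate_learning(config: NetworkConfig,
                      learning: LearningConfig,
                      forcings: Optional[Sequence] = None,
                      learn_theta: bool = True,
                      learn_omega: bool = False,
                      duration: float = 100.0,
                      state0=None,
                      stride: int = 10,
                      record_theta: bool = True) -> Trajectory:
    """Run the network with Hebbian theta learning (and optionally joint
    frequency adaptation) switched on; theta and omega traces are recorded.

    Training operates in the weak-coupling regime: the lateral magnitudes
    must stay well below the forcing amplitudes, otherwise the coupling
    perturbs the phases it is trying to read out (a warning is logged)."""
    A, _ = config.weight_matrices()
    if learn_theta and forcings is not None:
        amps = [f.I0 for f in forcings if f is not None and f.kind != "none"]
        if amps and A.max() > 0.1 * min(amps):
            log.warning("lateral magnitude A=%g is not << forcing amplitude %g; "
                        "theta learning may be biased", A.max(), min(amps))
    return simulate_network(config, state0=state0, forcings=forcings,
                            duration=duration, stride=stride,
                            learn_theta=learn_theta, learn_omega=learn_omega,
                            learn_A=not learning.freeze_magnitude,
                            tau_w=learning.tau_w, record_theta=record_theta)


def circular_distance(a: float, b: float, period: float) -> float:
    """Minimal circular distance between ``a`` and ``b`` modulo ``period``."""
    d = (a - b) % period
    return float(min(d, period - d))


def power_angle_distance(theta: float, target: float,
                         omega_i: float, omega_j: float,
                         max_turns: int = 30) -> float:
    """Distance between a learned power-coupling angle and its target,
    modulo the lattice 2*pi*(a*w_i + b*w_j), a, b integers.

    Whole phase turns accumulated by either oscillator shift the learned
    angle by lattice points; they cancel in any cosine readout, so two
    angles differing by a lattice point encode the same observable phase
    relationship.
    """
    two_pi = 2.0 * np.pi
    best = np.inf
    for a in range(-max_turns, max_turns + 1):
        d = circular_distance(theta, target + two_pi * a * omega_i,
                              two_pi * omega_j)
        if d < best:
            best = d
    return float(best)
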