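"""Frequency adaptation of a forced Hopf oscillator.

A supercritical Hopf oscillator driven by a sinusoid can pull its natural
frequency onto the forcing frequency.  With a real drive ``I0*sin(w0*t+phi)``
the update is ``omega_dot = -eps*I(t)*sin(phi)``; with a complex drive
``I0*exp(i(w0*t+phi))`` it is ``omega_dot = -eps*I0*sin(phi - w0*t - phi0)``,
equivalently written through the real and imaginary parts of the input.
Adapted frequencies are floored at a small positive value because power
coupling divides by omega.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import DEFAULT_DT, OscillatorParams, OscillatorState, Trajectory, _forcing_tuple


@dataclass
class ForcingSignal:
    """External drive: amplitude ``I0``, frequency ``omega0`` (rad/s), offset
    ``phase_offset`` (rad).  ``kind`` is one of ``real-sinusoid``,
    ``complex-sinusoid``, ``error-feedback`` (reservoir use) or ``none``."""

    I0: float = 1.0
    omega0: float = 1.0
    phase_offset: float = 0.0
    kind: str = "complex-sinusoid"

    def __post_init__(self) -> None:
        if self.I0 < 0:
            raise ValueError("forcing amplitude must be non-negative")
        allowed = {"real-sinusoid", "complex-sinusoid", "error-feedback", "none"}
        if self.kind not in allowed:
            raise ValueError(f"kind must be one of {sorted(allowed)}")


def _adapt(params, state0, forcing, eps, duration, dt, stride, omega_rule):
    n_steps = int(round(duration / dt))
    fk, I0, wf, pf = _forcing_tuple(forcing)
    rec_r, rec_p, rec_w = _kernels.single_oscillator(
        params.alpha, params.beta1, params.beta2, params.eps_sat, params.omega,
        state0.r, state0.phi, dt, n_steps,
        fk, I0, wf, pf, eps,
        True, omega_rule, stride)
    t = _kernels.record_times(n_steps, stride, dt)
    return Trajectory(t=t, r=rec_r[:, None], phi=rec_p[:, None],
                      omega=rec_w[:, None], dt=dt * stride)


def adapt_frequency_real(params: OscillatorParams,
                         state0: OscillatorState,
                         forcing: ForcingSignal,
                         eps: float,
                         duration: float,
                         dt: float = DEFAULT_DT,
                         stride: int = 1) -> Trajectory:
    """Adapt omega under a real sinusoidal drive (records the omega series)."""
    if forcing.kind != "real-sinusoid":
        raise ValueError("adapt_frequency_real requires a real-sinusoid forcing")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    return _adapt(params, state0, forcing, eps, duration, dt, stride, 0)


def adapt_frequency_complex(params: OscillatorParams,
                            state0: OscillatorState,
                            forcing: ForcingSignal,
                            eps: float,
                            duration: float,
                            dt: float = DEFAULT_DT,
                            stride: int = 1,
                            omega_rule: str = "sin") -> Trajectory:
    """Adapt omega under a complex sinusoidal drive.

    ``omega_rule`` selects between the closed sine form of the update and the
    Re/Im form; the two are the same expression and produce identical traces
    to rounding error.
    """
    if forcing.kind != "complex-sinusoid":
        raise ValueError("adapt_frequency_complex requires a complex-sinusoid forcing")
    rule = {"sin": 0, "cartesian": 1}[omega_rule]
    return _adapt(params, state0, forcing, eps, duration, dt, stride, rule)


def terminal_omega(traj: Trajectory, frac: float = 0.05, index: int = 0) -> float:
    """Terminal adapted frequency: mean of omega over the final ``frac`` of
    the recorded samples (smooths the residual ripple at the forcing
    period)."""
    if traj.omega is None:
        raise ValueError("trajectory has no omega series")
    n = max(1, int(round(frac * len(traj.t))))
    return float(np.mean(traj.omega[-n:, index]))
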