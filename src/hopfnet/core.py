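"""Canonical Hopf oscillator over the complex plane.

The single-unit model is ``zdot = z(alpha + i*omega + beta1*|z|^2 +
eps_sat*beta2*|z|^4/(1 - eps_sat*|z|^2))`` with state ``z = r*exp(i*phi)``.
The package integrates in polar coordinates by forward Euler with an
unwrapped phase; the Cartesian form is equivalent and is used in the test
suite as an independent oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels

log = logging.getLogger(__name__)

DEFAULT_DT = 1e-3  # seconds


@dataclass
class OscillatorParams:
    """Regime parameters of one Hopf oscillator.

    ``beta1`` is the signed cubic coefficient, so the supercritical preset is
    ``alpha = mu > 0, beta1 = -1, beta2 = 0`` giving a stable limit cycle at
    radius sqrt(mu).  ``omega`` is the natural frequency in rad/s and must be
    positive for any oscillator taking part in power coupling.
    """

    alpha: float = 1.0
    beta1: float = -1.0
    beta2: float = 0.0
    eps_sat: float = 0.0
    omega: float = 1.0

    @classmethod
    def supercritical(cls, mu: float = 1.0, omega: float = 1.0) -> "OscillatorParams":
        return cls(alpha=mu, beta1=-1.0, beta2=0.0, eps_sat=0.0, omega=omega)

    @property
    def mu(self) -> float:
        return self.alpha


@dataclass
class OscillatorState:
    """Polar state; ``phi`` is unwrapped (never reduced mod 2*pi)."""

    r: float = 1.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("radius must be non-negative")

    @property
    def z(self) -> complex:
        return self.r * np.exp(1j * self.phi)


@dataclass
class Trajectory:
    """Recorded time series of one simulation.

    ``r`` and ``phi`` have shape (n, N).  Optional series (natural
    frequencies, lateral weight angles, readout weights, output and error)
    are present when the producing simulation recorded them.  All series
    share the time grid ``t``.
    """

    t: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    omega: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    alpha: Optional[np.ndarray] = None
    output: Optional[np.ndarray] = None
    error: Optional[np.ndarray] = None
    epoch_error: Optional[np.ndarray] = None
    dt: float = DEFAULT_DT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("r", "phi", "omega", "alpha", "output", "error"):
            arr = getattr(self, name)
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"series '{name}' does not match the time grid")

    @property
    def n_oscillators(self) -> int:
        return self.r.shape[1]

    @property
    def z(self) -> np.ndarray:
        return self.r * np.exp(1j * self.phi)

    def to_frame(self):
        """Flat pandas DataFrame (t, r_k, phi_k, [omega_k, alpha_k, ...])."""
        import pandas as pd

        data = {"t": self.t}
        for k in range(self.n_oscillators):
            data[f"r_{k}"] = self.r[:, k]
            data[f"phi_{k}"] = self.phi[:, k]
        if self.omega is not None:
            for k in range(self.n_oscillators):
                data[f"omega_{k}"] = self.omega[:, k]
        if self.alpha is not None:
            for k in range(self.n_oscillators):
                data[f"alpha_{k}"] = self.alpha[:, k]
        if self.output is not None:
            out = np.atleast_2d(self.output.T).T
            for k in range(out.shape[1]):
                data[f"P_{k}"] = out[:, k]
        if self.error is not None:
            err = np.atleast_2d(self.error.T).T
            for k in range(err.shape[1]):
                data[f"e_{k}"] = err[:, k]
        return pd.DataFrame(data)


def radial_velocity_field(r, params: OscillatorParams):
    """Vectorized radial velocity alpha*r + beta1*r^3 + eps*beta2*r^5/(1-eps*r^2)."""
    r = np.asarray(r, dtype=float)
    f = params.alpha * r + params.beta1 * r ** 3
    if params.beta2 != 0.0:
        denom = 1.0 - params.eps_sat * r ** 2
        if np.any(np.abs(denom) < 1e-12):
            raise ZeroDivisionError("radial field singular: eps_sat * r^2 == 1")
        f = f + params.eps_sat * params.beta2 * r ** 5 / denom
    return f


def radial_derivative(r: float, params: OscillatorParams) -> float:
    """Scalar radial velocity at radius ``r`` (1/s).

    Requires ``r >= 0`` and, when ``eps_sat > 0``, ``r < 1/sqrt(eps_sat)``.
    """
    if r < 0:
        raise ValueError("radius must be non-negative")
    if params.eps_sat > 0 and r >= 1.0 / np.sqrt(params.eps_sat):
        raise ValueError("radius beyond the quintic saturation singularity")
    return float(radial_velocity_field(r, params))


def classify_regime(params: OscillatorParams) -> str:
    """Classify the autonomous regime of the oscillator.

    Returns one of ``critical-hopf``, ``supercritical-hopf``,
    ``supercritical-double-limit-cycle``, ``subcritical-double-limit-cycle``
    or ``other``.  The double-limit-cycle subcases are separated by the sign
    of the local maximum of the radial velocity field, located by a numeric
    scan over (0, 1/sqrt(eps_sat)).
    """
    a, b1, b2 = params.alpha, params.beta1, params.beta2
    if a == 0 and b1 < 0 and b2 == 0:
        return "critical-hopf"
    if a > 0 and b1 < 0 and b2 == 0:
        return "supercritical-hopf"
    if a < 0 and b1 > 0 and b2 < 0 and params.eps_sat > 0:
        r_max = 1.0 / np.sqrt(params.eps_sat)
        grid = np.linspace(1e-6, 0.999 * r_max, 4001)
        f = radial_velocity_field(grid, params)
        interior = (f[1:-1] >= f[:-2]) & (f[1:-1] >= f[2:])
        if not np.any(interior):
            return "other"
        local_max = float(np.max(f[1:-1][interior]))
        if local_max > 0:
            return "supercritical-double-limit-cycle"
        return "subcritical-double-limit-cycle"
    return "other"


def integrate_single(params: OscillatorParams,
                     state0: OscillatorState,
                     duration: float,
                     dt: float = DEFAULT_DT,
                     forcing: Optional["ForcingSignal"] = None,
                     eps: float = 1.0,
                     stride: int = 1) -> Trajectory:
    """Forward-Euler trajectory of a single (optionally forced) oscillator.

    ``forcing`` is a :class:`~hopfnet.adaptation.ForcingSignal`; the natural
    frequency stays fixed here (see :mod:`hopfnet.adaptation` for adaptive
    runs).  If the radius would go negative within a step it is clamped to 0
    and the event is logged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must cover at least one step")
    n_steps = int(round(duration / dt))
    fk, I0, wf, pf = _forcing_tuple(forcing)
    rec_r, rec_p, rec_w = _kernels.single_oscillator(
        params.alpha, params.beta1, params.beta2, params.eps_sat, params.omega,
        state0.r, state0.phi, dt, n_steps,
        fk, I0, wf, pf, eps,
        False, 0, stride)
    if np.any(rec_r == 0.0) and state0.r > 0:
        log.info("radius clamped at 0 during integration")
    t = _kernels.record_times(n_steps, stride, dt)
    return Trajectory(t=t, r=rec_r[:, None], phi=rec_p[:, None],
                      omega=rec_w[:, None], dt=dt * stride)


def _forcing_tuple(forcing):
    """Map an optional ForcingSignal onto kernel scalars."""
    if forcing is None:
        return _kernels.FORCE_NONE, 0.0, 0.0, 0.0
    kind = {"none": _kernels.FORCE_NONE,
            "real-sinusoid": _kernels.FORCE_REAL,
            "complex-sinusoid": _kernels.FORCE_COMPLEX}[forcing.kind]
    return kind, forcing.I0, forcing.omega0, forcing.phase_offset
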