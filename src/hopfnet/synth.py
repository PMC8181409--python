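"""Synthetic teaching-signal generators.

Covers the study inputs: exact finite sums of sinusoids, band-limited
aperiodic signals with a continuous spectrum below a cutoff (an EEG-like
surrogate), multichannel sets sharing one spectrum with channel-specific
amplitudes/phases, and the zero-phase low-pass step applied to recorded
data.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .core import DEFAULT_DT
from .reservoir import TeachingSignal

TWO_PI = 2.0 * np.pi


@dataclass
class SpectrumSpec:
    """Spectral recipe: explicit (amplitude, frequency rad/s, phase rad)
    components, or a random band spectrum (``band`` in Hz,
    ``n_components``, ``seed``)."""

    components: Optional[List[Tuple[float, float, float]]] = None
    band: Optional[Tuple[float, float]] = None
    n_components: Optional[int] = None
    seed: Optional[int] = None
    f_knee: float = 1.0  # Hz; 1/f-style amplitude envelope knee

    def realize(self) -> List[Tuple[float, float, float]]:
        """Concrete component list (deterministic for a given seed)."""
        if self.components is not None:
            comps = [(float(a), float(w), float(p)) for a, w, p in self.components]
            if any(a < 0 for a, _, _ in comps):
                raise ValueError("amplitudes must be non-negative")
            if any(w <= 0 for _, w, _ in comps):
                raise ValueError("frequencies must be positive")
            return comps
        if self.band is None or self.n_components is None:
            raise ValueError("need either explicit components or (band, n_components)")
        lo, hi = self.band
        if lo >= hi:
            raise ValueError("degenerate band")
        rng = np.random.default_rng(self.seed)
        f = rng.uniform(lo, hi, self.n_components)  # Hz
        amp = 1.0 / (1.0 + f / self.f_knee)
        ph = rng.uniform(0.0, TWO_PI, self.n_components)
        return [(float(a), float(TWO_PI * fk), float(p))
                for a, fk, p in zip(amp, f, ph)]


def gen_multisine(spec: SpectrumSpec, duration: float, dt: float = DEFAULT_DT,
                  domain: str = "real") -> TeachingSignal:
    """Exact sampled sum of sinusoids (cosines, or complex exponentials)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if domain not in ("real", "complex"):
        raise ValueError("domain must be 'real' or 'complex'")
    comps = spec.realize() if (spec.components or spec.band) else []
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if domain == "complex":
        out = np.zeros(n, dtype=complex)
        for a, w, p in comps:
            out += a * np.exp(1j * (w * t + p))
    else:
        out = np.zeros(n)
        for a, w, p in comps:
            out += a * np.cos(w * t + p)
    return TeachingSignal(samples=out, dt=dt,
                          meta={"components": comps, "domain": domain,
                                "seed": spec.seed})


def random_band_spectrum(band: Tuple[float, float], n_components: int,
                         seed: Optional[int] = None,
                         f_knee: float = 1.0) -> SpectrumSpec:
    """Random continuous-band spectrum: frequencies uniform on ``band`` (Hz),
    amplitudes decaying as 1/(1 + f/f_knee), phases uniform."""
    spec = SpectrumSpec(band=band, n_components=n_components, seed=seed,
                        f_knee=f_knee)
    return SpectrumSpec(components=spec.realize(), seed=seed, f_knee=f_knee,
                        band=band, n_components=n_components)


def gen_eeg_like(band: Tuple[float, float], n_components: int,
                 duration: float, dt: float = DEFAULT_DT,
                 seed: Optional[int] = None) -> TeachingSignal:
    """Band-limited aperiodic signal with a continuous spectrum below the
    cutoff, normalized to unit RMS — a stand-in for low-pass-filtered
    resting EEG (synthetic; it has none of real EEG's nonstationarity)."""
    if band[1] > 0.5 / dt:
        raise ValueError("band exceeds the Nyquist frequency")
    spec = random_band_spectrum(band, n_components, seed=seed)
    sig = gen_multisine(spec, duration, dt, domain="real")
    rms = float(np.sqrt(np.mean(sig.samples ** 2)))
    if rms > 0:
        sig.samples = sig.samples / rms
        sig.meta["components"] = [(a / rms, w, p)
                                  for a, w, p in sig.meta["components"]]
    sig.meta["band"] = band
    return sig


def gen_multichannel(base: SpectrumSpec, M: int,
                     amp_range: Tuple[float, float],
                     seed: Optional[int] = None,
                     duration: float = 20.0, dt: float = DEFAULT_DT):
    """M channels sharing the base frequencies, with per-channel random
    amplitudes (uniform on ``amp_range``) and phases (uniform on [0, 2pi))."""
    from .generative import MultichannelTarget

    if M < 1:
        raise ValueError("M must be >= 1")
    comps = base.realize()
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    Y = np.zeros((n, M))
    chan_comps = []
    for m in range(M):
        rows = []
        for _, w, _ in comps:
            a = rng.uniform(*amp_range)
            p = rng.uniform(0.0, TWO_PI)
            Y[:, m] += a * np.cos(w * t + p)
            rows.append((float(a), float(w), float(p)))
        chan_comps.append(rows)
    return MultichannelTarget(Y=Y, dt=dt,
                              meta={"components": chan_comps, "seed": seed})


def lowpass(signal: TeachingSignal, cutoff_hz: float) -> TeachingSignal:
    """Zero-phase FIR low-pass copy (passband ripple < 1 %, stopband
    attenuation >= 40 dB at twice the cutoff)."""
    nyq = 0.5 / signal.dt
    if cutoff_hz >= nyq:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    width = min(cutoff_hz, nyq - 1.5 * cutoff_hz if nyq > 1.5 * cutoff_hz else cutoff_hz)
    numtaps, beta = sps.kaiserord(60.0, width / nyq)
    numtaps |= 1  # odd length -> exactly linear phase
    taps = sps.firwin(numtaps, 1.5 * cutoff_hz, window=("kaiser", beta), fs=1.0 / signal.dt)
    padlen = min(3 * numtaps, signal.samples.shape[0] - 1)
    filtered = sps.filtfilt(taps, [1.0], signal.samples, padlen=padlen)
    meta = dict(signal.meta)
    meta["lowpass_hz"] = cutoff_hz
    meta.pop("components", None)  # spectrum no longer the raw recipe
    return TeachingSignal(samples=filtered, dt=signal.dt, meta=meta)


def periodogram_peaks(sig: TeachingSignal, n_peaks: int):
    """(frequency rad/s, amplitude) of the strongest periodogram peaks —
    used for round-trip checks of the generators."""
    x = sig.samples
    n = len(x)
    spec = np.fft.rfft(x * np.hanning(n))
    freqs = np.fft.rfftfreq(n, d=sig.dt) * TWO_PI
    mag = np.abs(spec)
    peaks, _ = sps.find_peaks(mag)
    top = peaks[np.argsort(mag[peaks])[::-1][:n_peaks]]
    # parabolic interpolation for sub-bin frequency
    out = []
    for p in sorted(top):
        if 0 < p < len(mag) - 1:
            denom = mag[p - 1] - 2 * mag[p] + mag[p + 1]
            delta = 0.5 * (mag[p - 1] - mag[p + 1]) / denom if denom != 0 else 0.0
            # parabolic peak height corrects most of the scalloping loss
            height = mag[p] - 0.25 * (mag[p - 1] - mag[p + 1]) * delta
        else:
            delta = 0.0
            height = mag[p]
        f = freqs[p] + delta * (freqs[1] - freqs[0])
        amp = 2.0 * height / np.sum(np.hanning(n))
        out.append((float(f), float(amp)))
    return out
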