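"""Synthetic teaching signals: multisines, EEG-like band-limited noise,
multichannel sets, and the zero-phase low-pass step.
"""

import numpy as np

from hopfnet import gen_eeg_like, lowpass
from hopfnet.io import read_timeseries, write_timeseries

sig = gen_eeg_like(band=(0.2, 5.0), n_components=200, duration=10.0,
                   dt=1e-3, seed=0)
print(f"EEG-like surrogate: {len(sig.samples)} samples, "
      f"RMS = {np.sqrt(np.mean(sig.samples ** 2)):.3f}")

spec = np.abs(np.fft.rfft(sig.samples)) ** 2
f = np.fft.rfftfreq(len(sig.samples), d=sig.dt)
print(f"fraction of power above 5 Hz: {spec[f > 5].sum() / spec.sum():.2e}")

smooth = lowpass(sig, cutoff_hz=2.0)
print(f"after 2 Hz low-pass, RMS = "
      f"{np.sqrt(np.mean(smooth.samples ** 2)):.3f}")

write_timeseries(sig, "scratch_eeg_like.tsv")
back = read_timeseries("scratch_eeg_like.tsv")
print("delimited-text round trip lossless:",
      bool(np.array_equal(back.samples, sig.samples)))
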