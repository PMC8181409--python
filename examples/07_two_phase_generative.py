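"""Two-phase generative model: encode one channel, reconstruct five.

Phase 1 encodes the spectrum of a three-tone reference signal into a small
reservoir; phase 2 freezes the reservoir, runs it from z(0) = 1, and fits
complex feed-forward weights so five channels sharing the reservoir's
frequencies (random amplitudes/phases) are reconstructed.
"""

import numpy as np

from hopfnet import (LearningConfig, SpectrumSpec, gen_multichannel,
                     gen_multisine, phase2_fit, reconstruction_error,
                     train_reservoir)

comps = [(1.2, 4.0, np.pi / 3), (0.8, 8.78, np.pi / 7), (1.0, 12.35, np.pi / 5)]
signal = gen_multisine(SpectrumSpec(components=comps), duration=20.0, dt=1e-3)
learning = LearningConfig(tau_w=1e4, eta_omega=0.1, eta_alpha=1e-4)
trained, _ = train_reservoir(signal, N=3, learning=learning, mode="real",
                             epochs=15, omega_init=(5.0, 9.0, 13.0),
                             A_lateral=0.1, eps=0.5)
print("phase 1 learned omegas:", np.round(np.sort(trained.omegas), 3))

base = SpectrumSpec(components=[(1.0, w, 0.0)
                                for w in np.sort(trained.omegas)])
targets = gen_multichannel(base, M=5, amp_range=(0.5, 1.5), seed=0,
                           duration=20.0, dt=1e-3)
readout = phase2_fit(trained, targets, eta_K=3e-5, eta_zeta=1e-6, epochs=4000)
rel = reconstruction_error(trained, readout, targets)
print("phase 2 per-channel relative MSE:",
      [f"{x:.2e}" for x in rel])
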