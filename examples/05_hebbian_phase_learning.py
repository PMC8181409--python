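"""Hebbian learning of the power-coupling angle.

Two forced oscillators (5 and 10 rad/s, forcing offsets pi/4 and pi/6)
train their lateral weight angle; theta_12 learns the scaled offset
phi_1*w_2 - phi_2*w_1 of the drives.  Running with frequency adaptation as
well (the joint scheme) first pulls the natural frequencies onto the
forcing frequencies, then encodes the phase relation.
"""

import numpy as np

from hopfnet import run_experiment

forced = run_experiment("fig8c")
print("forced pair:")
print(f"  theta_12 learned  = {forced['theta12_end']:+.4f}")
print(f"  phi1*w2 - phi2*w1 = {forced['target']:+.4f}")
print(f"  circular error (mod 2*pi*w2) = {forced['error_mod']:.2e}")

joint = run_experiment("fig9")
print("joint frequency + weight learning:")
print(f"  omega ends = {np.round(joint['omega_end'], 3)} "
      f"(targets {joint['omega_targets']})")
print(f"  theta vs oscillators' own phases, circular error = "
      f"{joint['theta_vs_phases_error_mod']:.2e}")
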