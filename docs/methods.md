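# Methods

## Model

The unit is the canonical Hopf oscillator over the complex plane,
`ż = z(α + iω + β₁|z|² + ε_s β₂|z|⁴/(1−ε_s|z|²))` with state
`z = r·e^{iφ}`.  Regime classification follows the sign pattern of
(α, β₁, β₂); the two double-limit-cycle subcases are separated by the sign
of the local maximum of the radial velocity field, located by a numeric
scan over `(0, 1/√ε_s)` (no closed form is used).  Everything downstream
runs in the supercritical regime `ż = z(μ + iω − |z|²)` with a stable
limit cycle at `r = √μ`.

Three lateral couplings are implemented for oscillator *i* receiving from
*j*:

* **real** — `A cos(θ) · Re(z_j)` (θ ∈ {0, π} encodes the sign);
* **complex** — `A e^{iθ} · z_j` (equal natural frequencies; locks
  `φ_i − φ_j` at θ, radii at `√(μ+A)`);
* **power** — `A e^{iθ/ω_j} · z_j^{ω_i/ω_j}`, defined as
  `r^{ω_i/ω_j} e^{i(ω_i/ω_j)φ}` on the **unwrapped** phase.  Evaluating
  the non-integer power on a principal-branch argument would make the
  vector field discontinuous, which is why the integrator never reduces φ
  modulo 2π.

Power coupling stabilizes the normalized phase difference
`ψ_ij = φ_i/ω_i − φ_j/ω_j` (seconds) at `θ_ij/(ω_iω_j)` plus spurious
solutions where the summed coupling terms cancel without vanishing
individually.  `σ_ij = ψ_ij − θ_ij/(ω_iω_j)` is the deviation reported by
the basin scans.

## Numerics

Forward Euler in polar coordinates, default `dt = 1 ms`, is the defining
scheme; a Cartesian Euler integrator exists only as a test oracle (both
are first order; they agree to a few 10⁻³ over 10 s at moderate ω).
Radii are clamped at 0 from below and divisions by r floored at 1e−9;
adapted frequencies are floored at 1e−3 rad/s because power coupling
divides by ω.  Angular frequencies are rad/s internally; the generative
front-end converts Hz at its boundary.  Basin scans integrate all grid
points as one compiled batch, bit-identical to sequential runs;
non-converged points (trailing-window rate above 1e−4 s⁻¹ over the final
10 % of the run) are reported as NaN, and the steady values are clustered
by a 1-D agglomerative merge with a 0.05 s gap.

## Learning rules

The complex-coupling Hebb rule relaxes W toward `z₁z₂*`; the power
analogue toward `z_i (z_j*)^{ω_i/ω_j}`.  By default only the angle learns
(`Ȧ = 0`), so the angle encodes the observed (normalized) phase
relationship; magnitude dynamics exist but are exercised only in tests.
Because the realized weight depends on θ only through `e^{iθ/ω_j}`, and
because whole phase turns of either oscillator shift the learned θ by
`2π(aω_i + bω_j)` without changing any cosine readout, learned angles are
compared modulo that lattice (`power_angle_distance`); the plain
`mod 2πω_j` comparison is exact only when no turns are slipped, e.g. for
forced pairs without frequency adaptation.

Frequency adaptation uses the phase-projection rule
`ω̇ = −εI₀ sin(φ − ω₀t − φ₀)` (real-forcing variant
`ω̇ = −ε I(t) sin φ`); the adaptation basin is roughly ±50 % of the
forcing frequency at ε = 0.9, I₀ = 1.  Terminal ω is reported as the mean
over the final 5 % of samples to smooth the ripple at the forcing period.

## Reservoir training

N oscillators share the reconstruction error `e = D − P` with
`P = Σ α_i cos φ_i` (real mode) or `Σ α_i z_i` (complex mode);
`ω̇_i = −η_ω e sin φ_i`, `α̇_i = η_α e r_i cos φ_i`, lateral angles by the
power-coupling Hebb rule, all on one Euler clock.  Defaults:
`r(0)=1, φ(0)=0, α(0)=0`, initial frequencies spread evenly over a band
(or sampled uniformly and sorted, in the banded generative front-end).
The real-mode readout omits `r_i` as written; an `readout_with_r` option
provides the variant whose update and readout share the same regressor —
both converge to the same parameters here.

Two numerical points matter in long trainings:

* **Teaching-signal presentation.** Presenting a sampled chunk repeatedly
  restarts the signal each epoch; if the chunk does not hold an integer
  number of fundamental periods this injects a phase jump at every wrap,
  which is enough to keep the reservoir in a precessing, partially locked
  state with a large error floor.  For continuous presentations of a
  periodic multisine the kernel therefore synthesizes `D(t)` exactly at
  every step from the component list; finite-duration aperiodic signals
  keep the sampled, restart-per-epoch path, which is the intended
  protocol for them.
* **Angle consolidation.** While ω fluctuates, the Hebbian fixed point of
  θ_ij moves at a rate proportional to ω-ripple × unwrapped phase — after
  10⁵ s the phases are ~10⁶ rad, so θ cannot track it and random-walks.
  Training ends with a short (10 s) consolidation window in which ω and α
  are frozen, phases are reduced to their principal values, and only θ
  learns.  This lands θ on the principal representative of the final
  locked configuration.  The reduction matters: whole-turn offsets shift
  the realized weights by `e^{−2πi·nω_i/ω_j}` (not identity for
  non-integer ratios) and can strand the `z(0)=1` regeneration in a
  spurious basin.

**Regeneration** restarts the reservoir at `z_i(0) = 1` with the lateral
magnitudes raised to `A_retrieve` (default 0.1; training uses weak
coupling so the drives dominate, retrieval needs strong coupling so the
angles dominate).  An autonomous network is defined up to a common time
translation — the coupling constrains only the pairwise normalized phase
differences, leaving one neutral mode — so the regenerated output equals
the teaching signal up to a time shift set by the initial condition.
`regeneration_error` therefore minimizes the relative MSE over that shift
(grid search over one fundamental period, then refinement) and reports it
after a settling period (default: a 10 s window after 20 s); the unaligned
number is also available and is large even for ideal weights.

## Two-phase generative model

Phase 1 runs the real-mode reservoir on one reference channel with a
banded mask (`|i−j| < bandwidth` after sorting the sampled initial
frequencies), the finite signal repeated over epochs.  Phase 2 freezes the
reservoir, takes the phase trajectories of a single run from `z(0)=1`,
and fits `W^f_ij = K_ij e^{iζ_ij}` by batch gradient descent on
`½Σ_t(Y_d − Y_p)²` with `Y_p_i = Re Σ_j W^f_ij e^{iφ_j(t)}`; the update
signs are fixed so the iteration *descends* (verified against central
finite differences).  K is kept non-negative by the
`(K, ζ) → (−K, ζ+π)` symmetry.  Reconstruction reruns the frozen
reservoir from `z(0)=1` — identical initialization is what makes the
fitted phases reproducible.  Phase trajectories are computed once and
reused across all batch epochs.

## Synthetic data

`gen_multisine` produces exact sampled sums of cosines (or complex
exponentials).  `gen_eeg_like` emulates low-pass-filtered resting EEG as a
sum of `n` random tones, frequencies uniform on a band, amplitudes
following `1/(1 + f/f_knee)` with `f_knee = 1 Hz`, phases uniform,
normalized to unit RMS.  It is a band-limited stationary surrogate: it has
the right second-order spectral content but none of real EEG's
nonstationarity, artifacts or cross-channel geometry, so passing tests
demonstrate the machinery on signals with a continuous spectrum, not
clinical fidelity.  `gen_multichannel` shares one set of frequencies
across M channels with per-channel random amplitudes and phases.
`lowpass` is a zero-phase Kaiser-window FIR (60 dB design) with the
passband/stopband contract: <1 % passband ripple, ≥40 dB at twice the
cutoff.  All generators are pure functions of (spec, seed).

## Parameters and problem sizes

Study operating points are bundled as presets (`hopfnet.PRESETS`):
adaptation at ε=0.9, pair locks at A=0.05–0.5, scans at A=0.2 over
(0, 2π]ᴺ grids (pair: 0.5 spacing, 200 s; triple: 2π/8 spacing, 150 s —
the triple's slowest basins need more than 100 s at this coarse spacing),
Hebbian runs at τ_W=10³ with A=10⁻⁴, reservoir trainings at A=10⁻⁵,
η_ω=0.1, η_α=10⁻⁴, τ_W=10⁴, ε=0.5 for 10⁵ s (the α time constant is
2/η_α = 2·10⁴ s, so shorter runs underestimate amplitudes), and the
generative model at A=0.1, 15–30 epochs, η_K=3·10⁻⁵, η_ζ=10⁻⁶.  Tests
that only need the mechanism (not the study operating point) use
η_α=3·10⁻³ over 6000 s, which reaches the same fixed points.

## Known limitations

* With as many oscillators as spectral components and random initial
  frequencies, a strong component can capture the oscillator nearest a
  weak one; recovery of arbitrary three-component signals is reliable
  (≥ 18/20 in the randomized suite) only with an over-complete bank, whose
  amplitude estimate for a line is the summed α of the oscillators locking
  it.  Degenerate learned frequencies are flagged, never merged.
* Real-coupled pairs at incommensurate frequencies show entrainment
  tongues; the package only simulates them, it does not map the tongues.
* At the 30-epoch generative operating point on unit-RMS signals the
  readout magnitudes are still far from converged (η_α·T ≪ 1); the
  phase-1 output then matches the teaching signal in spectral shape
  (cosine similarity ≈ 0.87 below the cutoff) but not in power.  More
  epochs or a larger signal scale close the gap.
* Forward Euler is first order; halving dt halves transient errors, and
  equilibria (phase locks, learned parameters) coincide with the exact
  ones because Euler fixed points are fixed points of the flow.
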