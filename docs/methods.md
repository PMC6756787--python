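# Methods

## Model

A grid-cell module is a continuous attractor network. In one dimension it
is a double ring: two sub-populations (R, L) of N neurons each, with
preferred phases θ_i = i/N on the unit ring. The synaptic activation s_i
obeys

    τ ds_i/dt = −s_i + τ r_i,
    r_i = φ( Σ_j W_ij s_j + I0 ± b ± a Σ_ρ C_{μρ} ω_ρ ),

with φ(x) = max(x, 0)/τ, τ = 10 ms, I0 = 3, and Euler integration.
Connectivity is distance-dependent inhibition, w(θ) = (A/2N)(exp(−θ²/2σ²) − 1)
with A = 200, σ² = 0.1, evaluated at the periodic distance between
preferred phases, with the outgoing weights of R (L) shifted by +φ (−φ),
φ = 0.2. The recurrent input to a neuron is independent of its own
sub-population, so the full weight matrix consists of identical block-rows;
the implementation stores one block-row and reuses it, which is an exact
4× (2D: 16×) saving.

In two dimensions each module has four sub-populations (R, L, U, D) on a
√N×√N lattice over the rhombus spanned by u1 = (1, 0),
u2 = (1/2, √3/2) with periodic boundary conditions; weights use the torus
distance and amplitude A/4N², and R/L (U/D) shifts are ±(φ, 0) (±(0, φ))
in Cartesian phase coordinates. Lattice placement is a deterministic
regular grid (reproducibility and exact discrete-translation tests);
uniform-random placement would only add quenched disorder.

Differential drive ±b to the opposing sub-populations moves the bump:
a module integrates velocity. The drive is b_μ,q = γ_μ(V_q + η_μ,q), with
γ = 0.06·(1, λ, λ²) across modules, λ = √2, and white velocity noise of
intensity η (discretized as Gaussian deviates of standard deviation
η/√dt per step). λ = √2 is reconstructed from the shipped couplings
(C1 = −Cs/λ ≈ 14.14, C2 = −Cs·λ ≈ 28.28 with Cs = −20), which an integer
spacing ratio could not produce.

## Velocity coupling

Each module emits ω = (β/τ)(Σ_R s − Σ_L s) per channel — a linear readout
of its phase velocity — and receives a·Σ_ρ C_{μρ} ω_ρ as additional
velocity drive. The scale a = [β Σ_i φ′(W s̄ + I0)_i]⁻¹ = τ/(β n_act) is
computed once from the uncoupled steady bump and held fixed (recomputing
it per step changes nothing measurable at the shipped sizes); a·ω is
β-independent, and trajectories under β = 1 and β = 7.3 agree to 1e−10.
φ′(0) is taken as 0 (measure-zero set; no active neuron sits exactly at
threshold at the steady state). With the calibrated single-module gain α
(phase velocity per unit drive), α·a·ω ≈ θ̇ within 5% across the linear
range — the readout really is a phase-velocity estimate.

Because ω is a fixed linear functional of s, the coupling is equivalent
to all-to-all inter-module synapses of uniform magnitude aβC_{μρ}/τ whose
signs depend only on the pre/post sub-populations; the implementation
verifies the two forms agree entrywise to 1e−12. The coupling involves
velocities only, never phases: every combination of bump positions remains
a steady state (capacity preservation, tested as < 1e−3 drift over 5 s for
ten relative offsets).

Shipped coupling matrices: m = 2 as above; m = 3 tridiagonal with
C12 = −Cs/λ, C21 = C23 = 9.4, C32 = −Cs·λ, C13 = C31 = 0. Stability
requires every eigenvalue of C below 1 (the exponential-filter loop gain
crosses unity there); for complex spectra the criterion is applied to the
real part. The stiffest linearized mode of the coupled system sits at
(min eig(C) − 1)/τ ≈ −41/τ, so explicit Euler needs dt < 2τ/41 ≈ 0.49 ms;
the integrators guard dt against the spectral radius of C. Defaults:
dt = 0.1 ms (full scale), 0.25 ms (desk scale).

## Reduced phase dynamics and response tensor

The phases obey θ̇ = αb(t) + C(f∗θ̇) with f the unit-area exponential
filter of time scale τ; the integrator removes the convolution with the
auxiliary variable z = f∗θ̇ (ż = (θ̇ − z)/τ). For slow inputs
θ̇ = X b with X = α(I − C)⁻¹. α has no printed closed form; it is
calibrated by regressing measured phase velocity on ≥ 5 constant drive
levels (R² > 0.999 required; α ≈ 107 s⁻¹ per drive unit at the shipped
parameters, N-independent in 1D). For m = 2, X± = α/(1 − (Cs ± √(C1C2)))
give X+/X− = 41 exactly with the shipped values.

Grid spacings follow from the slow-input gains: λ_μ = 1/(X γ)_μ meters per
cycle. The joint-motion vector (components ∝ 1/λ_μ) is an eigenvector of X
to < 1e−3 relative residual for the shipped parameters. Driving module 1
alone moves both modules at the ratio X21/X11 = 28.28/21 ≈ 1.347 — close
to, but deliberately not exactly, λ = 1.414: the response to a
single-module input retains a small relative-mode component (X− > 0).
Module removal zeroes the couplings to and from one module while keeping
every self coupling; the removed module and its former neighbors all
increase their spacing.

The single-module velocity response is linear to ~0.5% for drives
|b| ≲ 0.03 and grows superlinearly beyond (gain +4% at b ≈ 0.054,
independent of N). This matters for realistic speeds: with γ3 = 0.12 a
sustained 0.45 m/s puts module 3 outside the linear range. Per-channel
speeds of a 2D forager are smaller than its speed, which keeps the 2D
experiments (and the 1D surrogates driven by one channel of a 2D path) in
the linear regime most of the time.

## Phase diffusion under spiking noise

In Poisson mode the rate term is replaced by spikes (counts per step
~ Poisson(r·dt), each incrementing s by 1 — the literal unit-impulse
reading of the synaptic dynamics; Poisson rather than Bernoulli sampling
is exact for any r·dt). Around the coupled steady state the drift is
linearized, J = −I/τ + diag(φ′(h))(W_blockdiag + K), where K is the
rank-limited coupling block (ω enters through s only, which is exact since
ω is linear in s). J has one soft eigenvalue per module and direction —
the attractor manifold. At finite N these are not exactly zero: the
rectification boundary of the bump leaves them at a few percent of 1/τ
(shrinking with N) while the first relaxation mode stays near 1/τ; the
manifold check therefore accepts |eig| < 0.1/τ with a required ×10
spectral gap. Tangents ds̄/dθ_μ come from central differences of
one-lattice-site translations (exact steady states); the left null vectors
are computed by deterministic block inverse iteration on Jᵀ and
bi-orthonormalized against the tangents (ν_μ·T_ρ = δ_μρ), making them
independent of solver scaling.

The diffusion tensor is D_{μρ} = ½ Σ_i ν_{μ,i} ν_{ρ,i} r̄_i (phase²/s),
symmetric positive semidefinite by construction, invariant under lattice
translations of the bumps and linear in the rates. Uncoupled, D is
isotropic; coupled (m = 2, shipped parameters), D+/D− ≈ 38.5 at N = 1000
with the major axis within 1° of the joint-motion direction. The computed
anisotropy is stable across N (38.3–39.2 for N = 100–1000) and across
sub-lattice bump positions, and sits close to — though not exactly at —
the response anisotropy X+/X− = 41: the two ratios agree only
approximately because D's symmetric eigenbasis differs from X's oblique
one. A Monte-Carlo estimator (covariance growth of phases over repeated
spiking runs, affine fit to absorb the constant variance floor from
estimator jitter and sub-τ free diffusion, bootstrap CIs) confirms the
tensor within sampling error at N ≥ 128 (single module) and N = 256
(coupled anisotropy within a factor 2 at 60 trials).

## Trajectories and decoding

The trajectory generator emulates a foraging rodent: Ornstein–Uhlenbeck
velocity (persistence time 1 s; stationary scale set so the mean speed is
0.2 m/s by default, within the 0.1–0.5 m/s range typical of freely moving
rats), kept inside the arena by a soft repulsive acceleration that ramps
up within a wall margin (12% of the arena edge by default) and is sized
to turn a ~3σ approach — the animal decelerates and turns near walls, as
real foragers do, rather than bouncing with a velocity discontinuity
(hard reflection remains only as a safety net for tail events; a
discontinuous bounce is an artifact no measured trajectory contains, and
it transiently desynchronizes the modules through the velocity filter).
Positions and velocities are finite-difference consistent by
construction. The generator does not emulate thigmotaxis, pauses, or head
direction; passing tests therefore speak to the dynamics under generic
smooth bounded exploration, not to any specific animal's statistics. 1D surrogate experiments use one coordinate of a 2D
path (itself an exactly reflected 1D path) so that per-module drive
amplitudes match what one channel of the 2D network would receive.

Receptive fields r̄_i(x) are measured from the steady state: the bump is
translated to the phase corresponding to each grid position
(θ_μ(x) = ((x − x_ref)/λ_μ) mod 1, anchored at the relaxed phases; 2D via
the lattice-coordinate map) using periodic linear interpolation of the
rest profile, with spacings measured from the network's own noiseless
velocity response rather than assumed from theory. Rates are floored at
1e−4 of each neuron's maximum so the log template is finite.

The decoder maintains per-neuron effective counts n_i(t) (running update
n ← n·e^(−Δ/τ_d) + spikes, exactly the exponential-kernel sum, τ_d = 10 ms)
and reads out x̂(t) = argmax_x Σ_i n_i ln r̄_i(x) on the grid every 10 ms,
ties to the lowest grid index; samples before the first spike are invalid,
not zero. A catastrophic readout error is a jump of the decoded position
larger than λ_min/2 between consecutive samples (no threshold is published
for this; λ_min/2 is far above decoder jitter and far below any alias
distance, and the success metric is insensitive to halving or doubling
it); success(t) is the fraction of trials with no such jump in (0, t].
The random-guess MSE baseline is the expected squared distance between the
true position and a uniform point of the arena, L²/12 + (x − L/2)² per
dimension.

Scale note: the 1D three-module code with λ = √2 is structurally fragile
for decoding because λ1 = 2λ3 exactly — positions 2kλ3 apart are aliases
of modules 1 and 3 jointly, leaving only module 2 to disambiguate (margin
as small as 0.06 phase at ~0.8 m). In 2D an alias must coincide in both
coordinates and the nearest candidates carry ~0.42 phase of module-2
mismatch, which is why the decoding experiments (like the published ones)
are two-dimensional; the 1D decoder is still exposed for study.

## Problem sizes and presets

Full scale mirrors the reference setting: N = 1000 per 1D sub-population
(64² in 2D), dt = 0.1 ms, 100 trials, 20 s horizons. The desk preset —
used by the test suite and examples — is N = 200 (1D) / 16² (2D),
dt = 0.25 ms, 10–15 trials, 6–20 s, chosen so every pipeline stays
faithful at interactive runtimes; the diffusion anisotropy, tracking
ratios and slope reductions computed at desk scale agree with the
full-scale values to within a few percent. The decoding arena is 1 m
(2D), within the unambiguous range of the 2D code at the measured
spacings (≈ 0.70/0.49/0.32 m at N = 16²).

## Known limitations

- Rectified-linear rate neurons and literal unit spike increments; no
  conductances, no synaptic depression/facilitation, no learning of W.
- The coupling matrices for m > 3 are not optimized here; user-supplied C
  is accepted and screened for stability only.
- The finite-N soft modes mean the linearized diffusion tensor carry a small
  systematic uncertainty (the D+/D− value 38.5 vs the response-theory 41
  bounds its scale).
- The trajectory generator is statistically, not behaviorally, realistic.
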