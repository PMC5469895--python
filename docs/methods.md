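# Methods

## Intrafusal fiber model

Each of the three intrafusal fiber types (bag₁, bag₂, chain) is modelled
with the same structure: a purely elastic sensory region (stiffness K_SR,
rest length L₀SR) in series with a polar region consisting of a spring
(K_PR, L₀PR) in parallel with a damped contractile element. The contractile
element produces an active force Γ and a damping force
β·C·(L_PR − R)·sign(L̇_PR)·|L̇_PR|^a, with β and Γ affine in the fusimotor
activations (dynamic for bag₁, static for bag₂/chain). Because both regions
carry the same tension, eliminating L_PR = L − L₀SR − T/K_SR (instantaneous
sensory-region equilibrium) turns the force balance into a single
first-order ODE in the tension T whose only inputs are L, L̇ and the two
activations. Accelerations are deliberately not an input: the second-order
variant needs L̈, which is unavailable or hopelessly noisy when lengths come
from numerically differentiated encoder readings.

One derivation detail deserves emphasis: inverting the damping law for the
polar-region velocity gives L̇_PR = signpow(·, **1/a**) of the normalized
force excess — the reciprocal of the damping exponent. Using the damping
exponent a itself at this point (an easy slip when rearranging) collapses
the velocity sensitivity by orders of magnitude: the dynamic-drive ramp
response then barely rises above its plateau, instead of the large
elongation-phase Ia peak that is the signature of the organ. The
implementation uses 1/a.

With a < 1 the flow near an equilibrium behaves as u̇ ∝ −u^{1/a}, so
convergence to a passive equilibrium is algebraic rather than exponential:
fast from large perturbations, asymptotically slow below ~10⁻³ of the
tension scale. Tests therefore check exact stationarity of the closed-form
equilibrium, monotone contraction toward it, and reserve tight (1e−6)
convergence checks for the linear a = 1 case, where the model reduces to a
two-spring-dashpot system with relaxation time τ = βC·d₀ / (K_SR(1+K_PR/K_SR)),
d₀ = L − L₀SR − R − T*/K_SR.

### Afferent rate maps

bag₁ contributes G·[T/K_SR − (L_N^SR − L₀SR)] to the primary channel. bag₂
and chain contribute
G·{X·(L_sec/L₀SR)·[T/K_SR − (L_N^SR − L₀SR)] + (1−X)·(L_sec/L₀PR)·[L − T/K_SR − L₀SR − L_N^PR]};
the polar term is normalized by the polar rest length L₀PR, which keeps
secondary rates in the physiological range and makes them vanish for
contracted fibers. The secondary rate is the direct sum of bag₂ and chain;
the primary rate applies partial occlusion: the larger of (bag₁, II) passes
in full and the smaller is scaled by S (default 0.156). Both rates are
clamped at zero before spike generation — Poisson intensities must be
non-negative; the model can produce negative pre-clamp values below the
sensory-zone thresholds.

### Numerical integration

Forward Euler at a fixed external step (default δt = 1 ms, matching typical
spiking-simulator clocks), subdivided into `n_substeps` internal steps
(default 10) with inputs held constant. The scheme is first order; the
Richardson test verifies the error halves with the step. When the
polar-region length approaches the damping pole L_PR = R within 1e−9 L₀ the
denominator is clamped to the signed epsilon and a warning is emitted; this
keeps the flow finite while preserving its sign. Initial tensions are set on
the passive-equilibrium manifold at L(0) to avoid startup transients.

## Fusimotor spike integration

γ-motoneuron spikes are integrated per channel with exponential decay
(exact per-step factor e^(−δt/τ)) followed by one jump f ← f + r(1 − f)
per spike, applied sequentially so f ∈ [0, 1] holds by construction; the
decay-then-jump order is fixed for reproducibility (the alternatives differ
at O(δt)). Defaults r = 0.08, τ = 310 ms (dynamic) and r = 0.09, τ = 425 ms
(static). Chain fibers share the static integrator; their activation is the
bag₂ static activation scaled by 0.829, the mean ratio of the chain and
bag₂ saturation levels in the reference intrafusal model. Under regular
input at interval Δ the post-spike peak has the closed form
r / (1 − (1−r)e^(−Δ/τ)); the simulated counterpart used in tests is the
mean of per-cycle peaks (`cycle_peak_average`) — the time average over a
cycle is systematically ~2% lower than the peak and is not the quantity the
closed form describes. Under Poisson input at rate ν the stationary mean is
νr/(1/τ + νr), which differs from the regular-input peak by a few percent
(Jensen effect of the nonlinear jump); both closed forms are used as test
oracles.

## Calibration

The grid search scans 0.01 ≤ r ≤ 0.40 (step 0.01) and 100 ≤ τ ≤ 500 ms
(step 5 ms) — steps chosen to resolve the channel optima exactly. For each
cell and each stimulation frequency in {10, 50, 75, 100, 150} spikes/s the
integrator is driven for 3 s with regular spikes; errors are computed on a
trace smoothed by a centered moving average spanning one inter-spike
interval (this removes exactly the input-locked sawtooth). The magnitude
error compares the smoothed plateau (mean over the final 500 ms) with the
tabulated maximum; the shape error measures the deviation from 90% of the
trace's own plateau at the tabulated time-to-90%. Errors are summed per
frequency and averaged over frequencies; ties break toward smaller r, then
smaller τ. The reference table is an input, not a constant of the code: the
physiological maxima come from Hill-type activation kinetics that are
external to this package. `reference_from_integrator` builds a
self-consistent table (same plateau statistic, per-rate measured t90) for
parameter-recovery testing — consistency of the dataset statistic with the
search statistic is what makes recovery exact at grid resolution, and the
dataset type equally accepts a single per-channel t90 (e.g. 343 ms dynamic,
471 ms static) for externally supplied tables.

## Spike generation and populations

Two generators are provided: per-step Bernoulli (P{spike in step} =
rate·δt, clamped to 1; the natural method at a fixed 1 ms step) and
exponential-ISI sampling with thinning against the piecewise-constant rate.
They are statistically equivalent at small rate·δt (verified by chi-square
on bin-count distributions); at 1 ms and 100 spikes/s the Bernoulli ISI
distribution is geometric with CV √(1−p) ≈ 0.95, so the exact unit-CV
Poisson check applies to the ISI generator. A population computes the fiber
tensions once when `shared_tension` is set (equivalent to all spindles of a
muscle receiving the same fusimotor drive) and draws independent spikes per
unit; per-unit RNG streams are spawned from the population seed so unit i's
spikes are independent of the population size. Units are split
primary/secondary by a per-unit flag (first `round(n·primary_fraction)`
units are Ia).

## Geometry

Two-link chains (agonist/antagonist attached at link midpoints):
L_ago = √(l₁²/4 + l₂²/4 − (l₁l₂/2)cos θ) with exact derivative speed; the
antagonist length uses the attachment parameter s,
L_ant = √(l₁² + l₂² + 2s·sin((π−θ)/2)), and its speed is the exact analytic
derivative −s·cos((π−θ)/2)·θ̇/(2L_ant). A historical variant of the
antagonist speed (−2s·cos((π−θ)/2)·θ̇, not the derivative of the length
expression) is available behind `printed_antagonist_speed=True` for
replication; the exact derivative is the default because speeds must
integrate back to lengths. The semantics of s are opaque (units of
length²); it is exposed as a config parameter. Three-link chains with a
fixed angle α between the first two links reduce to an effective side
a = √((l₁/2)² + l₂² − l₁l₂cos α) and offset β from the law of cosines; the
mirrored muscle of the symmetric chain uses (−θ, −θ̇) via `side="right"`.
Lengths are normalized to L₀ at a rest angle (125° for the elbow protocol),
making the outputs scale-invariant in the link lengths. All speeds are
validated against central differences and the three-link length against a
planar forward-kinematics coordinate construction to 1e−12.

## Synthetic protocols

The ramp-and-hold generator reproduces the standard validation stretch:
0.95 L₀ for 1.1 s, ramp at 0.11 L₀/s for 1.1 s, hold for 1.1 s. The final
plateau is computed from the ramp kinematics (1.071 L₀); a `pin_plateau`
option instead rescales the ramp speed to land on a prescribed value (e.g.
a nominal 1.08 L₀) — the two specifications are mutually inconsistent by
0.009 L₀ and the kinematic reading is the default. Velocity samples at the
phase boundaries are assigned to the half-open starting phase, which makes
the trapezoidal integral of the velocity close on the total length change
to machine precision; for smooth sinusoids closure is O(δt²) and
consistency is checked by central differences instead. Sinusoidal joint
protocols support dwells at the extremes implemented by pausing a "motion
time" (0.5 Hz with 1 s dwells gives a 4 s period); the angular velocity is
the exact chain-rule derivative, continuous at dwell boundaries. γ drives
are regular (events at k/rate) or homogeneous Poisson (seeded exponential
intervals).

## Parameters

The shipped `cat_soleus` set is adapted from the cat soleus parameterization
of the published intrafusal model (Mileusnic et al. 2006, Table 1):
K_SR = 10.4649, K_PR = 0.15, R = 0.46, a = 0.3, L₀SR = 0.04, L₀PR = 0.76,
L_N^SR = 0.0423 (L₀ units; force per L₀ for stiffnesses), with per-fiber
damping/force coefficients and gains (bag₁: β₀ 0.0605, β₁ 0.2592, Γ₁
0.0289, G 20000; bag₂: β₀ 0.0822, β₂ −0.046, Γ₂ 0.0636, G 10000, X 0.7;
chain: β₂ −0.069, Γ₂ 0.0954). The damping constant C is kept symmetric
(1.0) — the reference model distinguishes lengthening/shortening values, a
refinement not carried here. `toy` provides round numbers for hand-checked
arithmetic. Every quantitative guarantee of the test suite is
parameter-set agnostic; the named set only determines the physiological
plausibility of the worked examples.

## What the synthetic data does and does not show

All inputs are generated: stretch protocols are ideal piecewise-analytic
trajectories, γ drives are regular or exactly Poisson, and reference
calibration tables are integrator-generated. Passing tests therefore
demonstrate internal correctness (closed-form agreement, statistical
consistency, exact parameter recovery, the qualitative fusimotor response
pattern) — not fidelity to recordings from real afferents, which would
require the reference model's Hill-type activation tables and experimental
rate data that are external to this package. Real encoder streams are
noisier than the generated trajectories; the model tolerates
single-step-differentiated velocities but tests do not quantify that
robustness.

## Known limitations

- Forward Euler only; stiff parameter choices need more substeps.
- No Golgi tendon organs, no extrafusal force production, no conduction
  delays or downstream synapse models.
- The fusimotor integrator under- and over-estimates activation below ~30
  and above ~150 spikes/s respectively relative to Hill-type kinetics; the
  identified (r, τ) are only as good as the reference table supplied.
- Geometry is planar, with midpoint attachments and a constant α in the
  three-link chain.
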