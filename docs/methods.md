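# Methods

## Model

The Caputo-Land system (CLS) generalizes the six-state Land model of human
cardiomyocyte contraction by replacing each state's time derivative with a
left Caputo fractional derivative of per-state order αᵢ ∈ (0, 2]. The states
and their couplings are unchanged from the reference model: thick-filament
cross-bridge cycling (U → W → S with distortion-dependent unbinding rates
γ_wu = γ_w|ζw| and γ_su, the latter zero in the neutral band ζs ∈ [−1, 0]),
thin-filament regulation (CaTRPN with Hill-type calcium binding, blocked
fraction B with cooperativity exponent n_Tm), and the distortion states
ζs, ζw driven by dλ/dt. The implicit unbound fraction is U = 1 − B − S − W.
Active tension is T = L_fac((ζs + 1)S + ζw W); L_fac combines the reference
maximal tension T_ref/r_s with the piecewise-linear length dependence
h(λ₀) = max(0, 1 + β₀(λ₀ + min(λ₀, 0.87) − 1.87)), evaluated once at the
sample's initial relative length and held constant per protocol.

The W-state influx is k_uw·U (the reference model's rate); a strict
alternative using k_ws·U is available via `w_influx_power_stroke_rate` for
comparison with formulations that write the influx with the power-stroke
rate.

### Parameters

Defaults (`src/caputoland/data/land_params.json`) are the published human
Land parameterisation, converted to per-second units: k_uw = 182 s⁻¹,
k_ws = 12 s⁻¹, duty ratios r_s = 0.25, r_w = 0.5, φ = 2.23, total distortion
amplitude 25, γ_s = 8.5 s⁻¹, γ_w = 615 s⁻¹, k_TRPN = 100 s⁻¹, n_TRPN = 2,
Ca50(λ=1) = 0.805 µM with length coefficient β₁ = −2.4, TRPN₅₀ = 0.35,
n_Tm = 2.2, k_u = 1000 s⁻¹, T_ref = 120 kPa, β₀ = 2.3. Derived rates
(k_su, k_wu, A_s = A_w, c_s, c_w, k_b) follow the reference model's
closed-form relations and are recomputed by the loader, so only base
parameters are configurable. The simulated preparation is a skinned cell in
activating solution: calcium is constant at 1.2 µM (≈2× the
length-corrected Ca50 at λ₀ = 1.1, i.e. ~80 % troponin occupancy — a firmly
activated but submaximal level), and the baseline relative sarcomere length
is λ₀ = 1.1 within a configurable physiological band [0.8, 1.2]. CaTRPN is
clamped at 1e−8 before the negative-exponent term in the B equation
(configurable; disabling the clamp turns a non-positive CaTRPN into an
error), which keeps order-space exploration finite without affecting any
physical trajectory.

### Time unit of the fractional operator

A Caputo operator is not invariant under time rescaling unless α = 1: if
rate constants keep fixed numerical values while α varies, the model depends
on the chosen unit. The CLS adopts the millisecond — the natural scale of
cross-bridge kinetics — as the reference timescale: rate constants keep
their per-millisecond numerical values as orders vary
(`land.FRACTIONAL_TIME_UNIT_S = 1e-3`). All public interfaces (grids,
protocol timings, step sizes) are in seconds; segment solvers rescale
internally (`protocol.solve_cls_segment`). At α = 1 the choice is
immaterial. This convention also keeps the calibration order boxes inside
the explicit scheme's stability region at both the 0.05-ms and the 1-ms
step; defining the operator on a per-second scale makes the thin-filament
equations numerically unstable across much of the search box.

## Solver

The multi-order Adams predictor–corrector (PECE) scheme advances every
component on a shared uniform grid t_j = t₀ + jh, each with its own
order-specific weights:

* predictor: yₙᴾ = T(tₙ) + hᵅ Σ_{j<n} ((n−j)^α − (n−j−1)^α)/Γ(α+1) · f_j
* corrector: yₙ = T(tₙ) + hᵅ (a_{n,0} f₀ + Σ_{0<j<n} β_{n−j} f_j + β₀ f(tₙ, yₙᴾ))

with β₀ = 1/Γ(α+2), βₙ = ((n−1)^{α+1} − 2n^{α+1} + (n+1)^{α+1})/Γ(α+2),
a_{n,0} = ((n−1)^{α+1} − n^α(n−α−1))/Γ(α+2). T(t) is the Caputo
initial-condition polynomial: y₀ for α ≤ 1, plus y'(t₀)(t−t₀) for α ∈ (1, 2],
with the initial derivative taken as the rhs at t₀ (zero when starting from
steady state; configurable to zero). The rhs is evaluated twice per step
(P-E-C-E); extra corrector iterations are configurable. At α = 1 the weights
reduce exactly to Euler prediction and trapezoidal correction, which the
test suite asserts to 1e−12 for n up to 1000.

Full memory is kept (O(N²) convolutions, vectorized per step): one 1-s
segment at the 0.05-ms step is 20 000 points and runs in a few seconds.
Short-memory truncation is available but off by default — it changes
fractional results (the omitted kernel weight decays only for α < 1) and is
never used in calibration. Divergence (non-finite values or |y| > 10³) flags
and truncates the trajectory instead of raising, because the order-range
scan deliberately probes unstable orders. Steady states are closed-form:
CaTRPN* = r/(1+r) with r = (Ca/Ca50)^{n_TRPN}, and S, W, B, U from the
linear rate balance at dλ/dt = 0.

Verification oracles: the one-parameter Mittag-Leffler function E_α(z),
summed by series in extended precision (mpmath) with adaptive truncation —
the float64 partial sums cancel catastrophically for strongly negative
arguments — plus closed-form two-component systems and a piecewise adaptive
LSODA integration (`reference_ode_solve`) that doubles as the "ODE-Land"
integer-order baseline in every comparison. Measured empirical orders of
accuracy on D^α y = −y are ≈ 1+α for α < 1 and ≈ 2 at α = 1.

## Protocol and preprocessing

The quick stretch-and-release input is λ(t): baseline λ₀, ramp to
λ₀(1 + stretch) at the window origin, hold for 1 s, symmetric ramp back,
1 s release — 2 s total, with the release segment owning the boundary
instant (half-open convention throughout). The default ramp is a C¹
raised-cosine of duration max(1 ms, 4h): a one-step linear ramp makes the
trapezoidal corrector under-integrate the distortion impulse by ~50 %, so a
smooth multi-step ramp is required for the integer-order CLS to match an
exact ODE solve to 1e−3; the exact piecewise-linear ramp remains available
(`ramp_shape="linear"`). Stretch fractions follow the experimental design:
0.5 %, 1 %, 2 %.

Preprocessing mirrors the experimental workflow: clip the 2-s activation
window (offsets recorded), split at the release instant, normalize to the
mean tension over the final 10 ms before stretch onset (for simulated traces
that start at the onset, the pre-stretch steady-state plateau). The
reference is stored so normalization is invertible and alternative rules
comparable. Traces on a different grid are linearly interpolated onto the
comparison grid.

Simulation of a full protocol: steady-state initialization, stretch segment
under α_stretch, Caputo memory reset at 1 s with the terminal state as the
new initial condition, release segment under α_release, concatenation, and
tension normalization by the pre-stretch plateau.

## Calibration

Order-range screening sweeps one state's α over 0.1–2.0 in steps of 0.1
(20 simulations per state) holding the others at 1, and classifies each
segment response. The under/overdamped judgement is operationalized
explicitly: divergent if the solver flagged it; underdamped if the response
shows more than 2 post-peak local extrema (2 % prominence); overdamped if it
has neither recovered half of its peak excursion by the segment end nor
flattened (last 20 % of the segment drifting < 5 % of the excursion counts
as settled — this admits responses that relax monotonically to a new
plateau). All thresholds are configurable and reported in the scan output.
The returned admissible interval is the longest contiguous stable run, ties
broken toward the interval containing α = 1.

The per-segment fit minimizes the MSE between simulated and measured
normalized tension with a real-coded genetic algorithm: population 50,
up to 700 generations, termination when MSE < 1e−5 (all defaults
configurable); search boxes per segment are the calibration bounds
(stretch: lower [0.9, 0.1, 0.8, 0.1, 0.1, 0.1], upper
[1.3, 1.6, 2.0, 2.0, 1.4, 1.3]; release: lower [0.1, 0.1, 0.8, 0.1, 0.6, 0.5],
upper [1.2, 1.5, 1.8, 1.9, 1.4, 1.3]). Internals, where the original
workflow relied on a toolbox's defaults, are specified exactly: tournament
selection (size 4), blend (BLX-0.5) crossover with probability 0.8, Gaussian
mutation with σ decaying linearly from 10 % to 0.5 % of the bound width,
5 % elitism, clipping to the box, and a stall criterion (no improvement
beyond the tolerance over 50 generations) so a converged search does not
burn the full generation budget. The initial population always contains the
all-ones vector, so the best individual can never be worse than the
integer-order baseline (up to solver tolerance) — the nesting guarantee.
Divergent candidates receive infinite fitness; if the entire initial
generation diverges the fit aborts with advice to review the bounds. Fits
are exactly reproducible for a fixed seed.

A subject-level fit runs the stretch segment first, seeds the release
simulation with the stretch fit's terminal state, fits the release segment,
reconsolidates the 2-s trace (the boundary jump is logged, not smoothed),
and reports CLS and ODE-baseline MSE/max-error on the same grid and
normalization, plus per-state fractionality labels: high iff |α − 1| > 0.2,
strictly (the boundary value 0.2 is labelled low). Cohort envelopes are
pointwise min/max of fitted traces within one protocol.

Two execution profiles are first class. `full`: population 50, 700
generations, h = 0.05 ms — the full calibration budget, hours-scale.
`ci`: population 16, 40 generations, h = 1 ms — the desk-scale budget used
by the test suite and the acceptance script; at this step the coarse-grid
discretization error is shared by data generation and fitting, so parameter
recovery is unaffected.

## Synthetic cohorts

The generator emulates the calibration dataset's statistical structure:
21 subjects split 5/11/5 across the 0.5 %/1 %/2 % protocols. Per-subject
fractional orders are drawn uniformly within the segment's calibration box
for the strongly fractional states W, CaTRPN and B; S and the distortion
orders stay at 1 (the sampling rule is configurable; cross-state
independence is assumed — real inter-subject covariance is unknown).
Candidate order pairs are accepted only if both simulated segments classify
stable (rejection sampling, capped at 50 retries with the most deviant state
reported on failure). Traces are resampled onto a 1-ms "experimental" grid
to emulate instrument sampling and exercise interpolation, then AR(1)
Gaussian noise is added: stationary standard deviation 2 % of the
pre-stretch plateau, lag-1 autocorrelation 0.8. Ground truth is stored in a
manifest beside the trace files; the loader cross-validates completeness in
both directions. Generation is a pure function of (spec, parameters, solver
settings, seed).

What the generator does not emulate: skinned-fiber artifacts, instrument
drift, the pre-activation waveform, inter-subject covariance of orders, or
variability in the base rate constants. Passing recovery tests therefore
demonstrates that the pipeline identifies fractional orders when the model
class is correct and noise is as modelled — not that real traces are free of
model misspecification.

## Numerical choices and limitations

* Step sizes: 0.05 ms reproduces the reference workflow; 1 ms is the
  desk-scale default. Problem sizes used by the tests and the acceptance
  script: 20 000-point segments for the fine-grid nesting check, 1000-point
  segments elsewhere; GA budgets of 16×40 (recovery) and 16×5
  (cohort nesting) evaluations.
* Tension sensitivity to the orders is strongly state-dependent at the
  default operating point: distortion orders > S > W > B > CaTRPN. The
  noiseless recovery experiment therefore uses the 2 % protocol and a
  termination tolerance of 1e−12 (the data are solver-consistent, so zero
  MSE exists exactly at the truth; the default 1e−5 tolerance would accept
  the seeded integer-order individual immediately). Orders of weakly
  exciting states (CaTRPN, and the distortions under richer sampling rules)
  are at the edge of identifiability from a single noiseless segment — a
  genuine property of the experiment, not of the optimizer.
* The α > 1 branch needs a first-derivative initial condition; it is the rhs
  at the segment start (exact for steady-state starts), configurable to
  zero.
* Determinism is bitwise for fixed seeds: the solver is pure numpy, the GA
  and noise use `numpy.random.default_rng(seed)`, and no parallelism is
  involved.
* Only the Caputo operator is implemented (no Riemann-Liouville or
  Grünwald-Letnikov), no adaptive stepping, no implicit/stiff FDE methods,
  and no re-fitting of the base Land parameters (skinned-to-intact
  recalibration of Ca50/n_Tm/k_uw/k_ws is out of scope).
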