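# Methods

## Model and assumptions

The package implements a two-layer multiscale model. The fast layer is a
population of N globally coupled active rotators with phases `phi_k` and
inputs `I_k = r1 + r2 nu_k`, where the `nu_k` are frozen standard-normal
draws; a single rotator is excitable (stable rest state, large response to
supra-threshold kicks) for `|I_k| < 1` and fires periodically beyond, via a
saddle-node-on-invariant-circle (SNIPER) bifurcation at `|I_k| = 1`. The
slow layer is a two-component resource `r = r1 + i r2` obeying a Hopf
normal form around a base level `s`, whose activity parameter `lam` relaxes
to `lambda0 + gamma A(t)`, with `A(t)` the population's mean phase
velocity. Both slow equations carry the scale separation `eps = eps' =
0.05` (kept as two separate fields; they default equal). The coupling is
evaluated through the Kuramoto order parameter `Z` (O(N)), algebraically
identical to the pairwise sine sum. Exact finite-N identity used throughout
and asserted in tests: `A = r1 + r2 mean(nu) − Im Z`.

Assumptions inherited by every analysis step: all-to-all coupling, Gaussian
heterogeneity, no noise, no delays; the mean-field (Ott–Antonsen) reduction
additionally assumes `N -> infinity` and restricts to the invariant
manifold where the phase-density Fourier coefficients are powers of the
local order parameter `z(I, t)`. Attractivity of that manifold is assumed,
not proven here.

## Layer analysis

**OA field.** The heterogeneity integral `Z = ∫ g(I) z(I) dI` is
discretized on a fixed grid in nu-space, so time-varying resources only
remap the inputs `I_m = r1 + r2 nu_m`. Default: M = 201 trapezoid nodes on
[−8, 8] (robust for the folded, kinked stationary profiles);
Gauss–Hermite (probabilists' scaling) available for smooth integrands. All
Gaussian quadratures truncate at 8 standard deviations (mass < 1e-15).
`|z_m| <= 1 + 1e-6` is a monitored invariant — a breach raises, it is never
clipped.

**Stationary states.** Inserting the stationary local order parameter
(unit-modulus rest states for `|I| < B`, partially coherent drifting states
for `|I| > B`) into the order-parameter integral gives the scalar
self-consistency function `p(B)` with the two integrals `p1, p2`. The
reference evaluation integrates in standardized coordinates with adaptive
QAGS (the sqrt edge behaviour at `|I| = B` is integrable); a fast vectorized
path uses the substitutions `I = B sin u` (excitable window) and
`I = ±B cosh u` (tails), which remove the singularities entirely and agree
with the adaptive path to ~1e-12 for order-one `r2`. Root finding scans
2000 log-spaced points in `B ∈ [1e-3, 1 + sigma + |r1| + 8 r2]`, brackets
sign changes, polishes with Brent, and doubles the scan resolution until
the root count stabilizes (fold proximity safeguard); roots closer than
1e-4 are flagged, never merged. Stationary macroscopic quantities come from
the closed forms `Z = (p2 − sigma R²) + i p1`, `R = sqrt(p1² + p2²)/B`, and
the full-quadrant `Theta = atan2(p1, p2 − sigma R²)` (the scalar-arctangent
form is quadrant-ambiguous). The stable rest branch (`cos Phi* >= 0`)
enters the population profile; the saddle does not appear in the stationary
density.

**Spectra.** The per-input Jacobian P and the global-feedback block Q are
closed forms; at frozen Z the flow is holomorphic in z, so P has the
Cauchy–Riemann structure and its eigenvalues are conjugate pairs — real
double eigenvalues `−sqrt(B² − I²)` on the excitable side, pure-imaginary
pairs `± i sqrt(I² − B²)` on the drifting side. Hence the continuous
spectrum is a cross: the real segment `[−B, 0)` plus an imaginary segment —
always stable or marginal. The discrete spectrum solves `det C(mu) = 0`;
the resolvent integral uses adaptive Gauss–Kronrod quadrature split at
`±B`, a 1e-6 exclusion margin around the (sampled) continuous spectrum, and
a two-tier tolerance (1e-7 during root search, 1e-10 for validation).
Isolated roots must satisfy `|det C| < 1e-8`. One subtlety: the
stability-deciding real eigenvalue of the coherent branch is *embedded* in
the continuous segment `[−B, 0)`, where det C is defined only as a boundary
value; such roots are located from sign changes of `Re det C(x + i 1e-3)`
and accepted under a 0.1 residual bound set by the Plemelj term. They are
genuine decay rates (the layer dynamics confirms the classification), but
no 1e-8 residual is attainable for them. Classification: sign of the
largest real part (1e-7 marginality band) x real-vs-complex leading
eigenvalue; search region Re ∈ [−2, 2], Im ∈ [0, 5], conjugates completed
by symmetry, deduplication at 1e-6.

**Folds, critical line, Hopf-like locus.** Folds solve `{p = 0, dp/dB = 0}`
by Newton, with analytic `dp/dB` (differentiating under the integral; the
boundary terms vanish). Fold detection at fixed `r2` bisects the root count
over `r1`; the continuation over `r2` is plain predictor–corrector with
step halving. At `sigma = 5, r2 = 1.2` the coherent pair (B1–B2) fold sits
at `r1 = 0.9678`. The operational critical line bisects `r1` on the
stationary-vs-oscillating classification of the layer started from the
incoherent state (200 time units, last 100 classified), giving
`r1* = 0.9686` at `r2 = 1.2` — the two definitions agree to ~1e-3.
The classifier calls a trajectory oscillating when the unwrapped mean phase
drifts by more than 2*pi or Im Z has peak-to-peak amplitude above 0.05; the
floor sits between genuine collective oscillations (order-one amplitude at
onset, SNIPER scenario) and the ~1e-2 non-decaying beating that the
discretized marginal continuous spectrum leaves around stationary states.
The third branch also changes stability in a Hopf-like scenario; at
`sigma = 5` the region where it carries a complex pair is the fold-over
pocket near `(r1, r2) = (1.0, 2.2)`, and the locus is traced by bisecting
the pair's real part in `r2` at fixed `r1` (crossing between
`r2 = 2.17` and `2.19` at `r1 = 0.99`).

## Slow-fast machinery

The averaged slow system reads the time-averaged layer activity from a
bilinear table over `(r1, r2)` (stationary cells refined with the closed
form `A = r1 − p1`). The coupled reduced system integrates the OA field
together with the slow resource equations in fast time, with
`A = r1 − Im Z`; this remains valid inside bursts, where averaging is not,
so dynamic experiments run on the reduced system or the full network, never
on the averaged one. The burst mechanism: while `(r1, r2)` is on the
oscillating side of the critical line, `A > 0` charges `lam`; past zero the
resource orbits the base level, recurrently crossing into the quiescent
region where `A` collapses and `lam` drains toward `lambda0 < 0`; the
spiral back toward `s` re-enters the active region. A trajectory is labeled
"steady" iff `max lam < 0` over the evaluation window, "bursting" if `lam`
additionally changes sign at least twice, else "active" (the recurrence
requirement separates bursting from permanently active tonic states).

**Initial states.** The base level `s` is an exact equilibrium of the
resource equation at every `lam`, so a run started exactly at `r = s` can
never develop the resource limit cycle. Experiments that must land in the
bursting basin therefore start displaced, `r(0) = s + 0.4, lam(0) = 0.15`;
steady-state preparations start at `r(0) = s + 0.05, lam(0) = lambda0`,
leaving the small residual displacement that any finite system's
fluctuations would provide (and that switching perturbations amplify).
Initial phases are i.i.d. uniform with a logged seed; one heterogeneity
draw is reused across regime comparisons. A deterministic "stratified"
sampling mode (equiprobable normal quantiles) is available and tightens
finite-size effects by about an order of magnitude.

**Experiments.** Adiabatic sweeps chain simulations, each warm-started from
its predecessor. The reference protocol is 7000 time units per step
averaging the last 5000, with step 0.002 in `s1`; the scaled protocol used
by the test suite divides the windows by 10 (700/500) and coarsens the step
to 0.02 — regime labels are insensitive to this (checked directly for the
probe points). Sweeps and switching run on the microscopic engine
(N = 1000, seed 42): the steady state at `s1 = 0.97` lies marginally beyond
the mean-field fold (0.9678), so its existence at criticality is a
finite-size feature, exactly as in the reference experiments at N = 5000 —
the infinite-N reduction has no stationary layer state there. Switching
protocols are applied exactly: reset replaces `lam` discontinuously; clamp
suspends the `lam` equation for the stated duration. Verdicts compare
regime labels over matched pre/post windows and record `lam` at the moment
of perturbation, because switching out of a burst can depend on the phase
at which the perturbation lands.

## Numerics

Two integrator paths everywhere: adaptive Dormand–Prince (rtol 1e-8, atol
1e-10) as the reference, and a fixed-step classical RK4 (dt = 0.01 fast
time units, numba-compiled, bit-reproducible) for long experiments and
regression tests; doubling the output sampling never changes the dynamics,
only the sampling. `A(t)` is always the exact instantaneous mean of the
analytic right-hand sides, never a finite difference. Phases integrate
unwrapped (only sin/cos of them enter the dynamics) and are wrapped for
output.

Problem sizes used by the test suite and examples: N = 1000 for full-system
experiments (N = 4000 stratified for the mean-field/microscopic coherence
comparison, which agrees to 2e-4 in R at stationary points — the 0.02
acceptance band is extremely conservative for stratified sampling),
M = 201 for OA trajectories, M = 80 Gauss–Hermite for fixed-point residual
checks, 2500-4000 fast time units for burst statistics.

## What the synthetic setup does and does not show

All inputs are generated by the model itself (there is no external data):
Gaussian heterogeneity, all-to-all coupling, deterministic dynamics.
Passing tests demonstrate the internal consistency of the analysis chain —
microscopic simulation, mean-field reduction, self-consistency roots,
spectra, bifurcation structure and the burst mechanism agree with one
another quantitatively. They do not speak to robustness under network
topology, noise, non-Gaussian heterogeneity, or parameter mismatch
(`eps' != eps` is supported but untested beyond defaults), nor to the
attractivity of the OA manifold from off-manifold initial conditions.

## Known limitations

* Near-homogeneous populations (`r2 <~ 1e-2`) stress the fast quadrature
  path; the adaptive path handles them but the default scan grid may need
  refinement for `r2 < 1e-3`.
* Embedded discrete eigenvalues are boundary-value zeros (see above): their
  imaginary part is set to zero by construction and their residual bound is
  loose; off-axis resonances hiding behind the continuous spectrum are not
  searched for.
* The cusp locator reports the closest approach of the two continued fold
  branches, not a solution of the codimension-two defining system
  (`d²p/dB² = 0` is reported as a residual, not solved for).
* Fold continuation assumes the fold curves are graphs over `r2` locally;
  past the turning point of the lower branch the curve is picked up again
  by the root-count scan rather than followed around the fold of folds.
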