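# Methods

## Model and assumptions

`rdgrow` solves the linear reaction–diffusion conservation law

    ∂C/∂t = D ∂²C/∂x² − ∂(Cv)/∂x + kC   on 0 < x < L(t),

with zero diffusive flux at both ends. Growth is *uniform*: the stretch
rate ∂v/∂x = σ(t) = L′(t)/L(t) is position-independent, the origin is
fixed (v(0, t) = 0), and the domain only elongates (L non-decreasing).
Spatially non-uniform growth, shrinkage, nonlinear reaction terms and
higher dimensions are out of scope. All quantities are dimensionless; no
unit system is imposed.

In the fixed coordinate ξ = x/L(t) the equation becomes

    ∂C/∂t = (D/L²(t)) ∂²C/∂ξ² + (k − σ(t)) C,

where growth acts twice: it weakens effective diffusion (1/L²) and dilutes
the density (−σC). The rescaled time T(t) = ∫₀ᵗ D/L²(s) ds reduces this to
the heat equation, solvable by separation of variables in the cosine basis
(the eigenbasis of the zero-flux Laplacian on [0, 1]).

## Exact evaluator

The unified series

    C(x, t) = (L(0)/L(t)) e^{kt} Σₙ aₙ cos(nπ x/L(t)) exp(−(nπ)² T(t))

uses the identity exp(∫₀ᵗ (k − σ) ds) = e^{kt} L(0)/L(t), valid for every
growth law, so one code path (`evaluate_exact`) covers static,
exponential, linear and custom growth. The literal per-case closed forms —
static exp(−D(nπ)²t/L² + kt); exponential exp(−D(nπ)²(1 − e^{−2αt})/(2αL(0)²)
+ t(k − α)); linear with the factor exp(−kL(0)/b) inside its coefficients
and exp(kL(t)/b) outside, plus an overall L(0)/L(t) — are kept as a
separate evaluator (`evaluate_case_formula`) purely as a cross-check. A
property test asserts pointwise equivalence to ≤ 1e−10 relative over random
parameter draws in all three cases; the linear case's equivalence is the
algebraic identity kL(t)/b − kL(0)/b = kt. The two evaluators were
confirmed numerically equivalent, so no discrepancy between the printed
forms and the unified form needed flagging.

Numerical choices:

- **Truncation.** Default n_max = 1000 modes, exposed everywhere as a
  parameter. At a step discontinuity (t = 0) the truncated series shows the
  usual Gibbs oscillation and may dip slightly below zero near x = β; no
  smoothing is applied, and the front-finding conventions below are defined
  to be robust to it.
- **Overflow guard.** The factor e^{kt} is handled in the log domain; a
  combined exponent above 700 raises an explicit overflow error in profile
  evaluation rather than returning infinities.
- **Coefficients.** Step coefficients use the closed form; general initial
  profiles are integrated by adaptive quadrature (oscillatory-weight rule
  for the cosine moments). The growth-free coefficients never absorb
  growth- or reaction-dependent factors.
- **Boundary evaluation for colonization.** Deep in the front tail the
  alternating boundary series Σ aₙ(−1)ⁿ exp(−(nπ)²T) cancels to ~1e−16 of
  its term magnitudes while strong production amplifies it by e^{kt} (up to
  ~1e13 in the high-production scenario). The colonization test therefore
  accumulates this single-point sum in extended (80-bit) precision,
  recomputes the step coefficients in that precision, and applies the
  growth factor in the log domain. Cross-validated in the tests against a
  method-of-images erfc representation of the heat solution, which is
  exact to full relative precision in the tail; double-precision summation
  alone would shift the high-production colonization time by ≈ 0.05 time
  units.

The two-term long-time truncation is provided for static domains only. On
growing domains T(t) saturates (exponential: D/(2αL(0)²); linear:
D/(bL(0))), higher modes never become negligible relative to the leading
ones, and truncation is unreliable at *every* time; the function refuses
with an explicit unsupported-case error rather than silently
approximating.

## Growth laws

`GrowthModel` implements length, stretch rate, velocity, rescaled time,
its saturation limit, and the inverse map t(T). The three analytic cases
use closed forms throughout, including the inverse (static TL²/D;
exponential −log1p(−2αL(0)²T/D)/(2α); linear TL(0)²/(D − TL(0)b)) — a
deliberate deviation from root-finding, since the closed forms are exact
and make the round-trip identity hold to machine precision. Custom laws
(any positive non-decreasing callable) get σ from a centered difference of
log L with relative step 1e−6, T from adaptive quadrature (rel. tol.
1e−11), and t(T) from bracketed Brent iteration with the bracket doubled
until it contains T (rel. tol. 1e−13); their saturation limit is reported
as unknown rather than guessed. Near saturation the inverse map is
intrinsically ill-conditioned (dt/dT ~ e^{2αt}/D), which bounds the
meaningful round-trip accuracy there; tests restrict fine-tolerance
round-trip checks to αt ≲ 5.

## Finite-difference reference solver

The fixed-domain equation is discretized with central second differences
(mesh δξ, 1/δξ integral) and backward Euler (step δt), with L and σ
evaluated at the *new* time level for a fully implicit, unconditionally
stable step. Zero-flux ends are closed by ghost-node mirroring
(C₋₁ = C₁), second-order and consistent with the cosine eigenbasis. Each
step solves one tridiagonal system with an in-house Thomas algorithm
(JIT-compiled; zero pivots are reported, though backward-Euler systems are
strictly diagonally dominant). Defaults δξ = δt = 0.001. Requested output
times are snapped to the nearest step multiple and the snapped time is
recorded.

The step initial condition is sampled half-open: a node exactly at x = β
(within 1e−12 relative) belongs to the zero side. Output on the reference
mesh agrees with the exact series to ≤ 2.3e−3 C₀ at t = 10 and 20 in the
mid-diffusivity scenario (tested bound 5e−3 C₀), converging monotonically
under mesh halving. The refinement difference between (δξ, δt) and halved
steps at the reference mesh is ≈ 1.1e−3 C₀ — dominated by the first-order
time error — so the grid-independence check's default pass tolerance of
1e−3 C₀ is strict at that resolution; callers can pass an explicit
tolerance.

## Fronts and colonization

The front is the *rightmost downward crossing* of the threshold ε, located
by linear interpolation between bracketing nodes of a 2001-node fixed-ξ
grid (default). Rightmost, so that Gibbs oscillations of the truncated
series near a discontinuity cannot pull the front left of the jump. At
t = 0 with a step initial condition the front is placed exactly at β — the
jump itself crosses every level in (0, C₀) — rather than read off the
oscillating series. If the density exceeds ε at the right boundary the
profile is flagged colonized (f = L(t)); if it is below ε everywhere,
extinct.

ε is an absolute density (default 0.01 with C₀ = 1, the published
convention), not normalized by C₀. Colonization at t★ means strictly
C(L(t★), t★) > ε; equality reports not colonized.

`colonization_time` scans [0, t_max] in 200 equal steps, then bisects the
first False→True bracket to a time tolerance of 0.01. All status
transitions seen on the scan are reported, and the earliest is refined —
permanence of colonization is checked empirically on the worked scenarios,
not assumed. An interval of colonization narrower than t_max/200 could in
principle be stepped over; the worked scenarios are nowhere near that
regime.

Scan-plus-bisection converges to the *exact* first crossing of the
criterion. The published approximate readings for the worked scenarios sit
up to ≈ 1–3 time units later than these exact crossings (e.g. the
high-diffusivity scenario crosses at t = 14.82; the wide-strip scenario at
13.00; the high-production scenario at 18.98; the ε = 0.015 case at
57.29), consistent with the space–time summaries having been inspected at
a coarse output cadence. The package reports the exact crossings.

## Synthetic scenarios

The built-in scenarios are the published parameter combinations — an
exponentially elongating domain with L(0) = 1, α = 0.1, C₀ = 1 and
(D, β, k) varied one at a time: D ∈ {1e−5, 1e−3, 1e−2} at β = 0.2,
k = 0.105; β = 0.75 at D = 1e−3; k = 1.705 at D = 1e−3 — plus static and
linear-growth (b = 0.05) demonstration cases. They are exact model inputs,
not data: passing tests show the solvers implement the stated mathematics
at these parameters, and say nothing about how well the *linear* model
approximates real enteric-nervous-system development, where proliferation
saturates, growth is non-uniform, and fronts interact nonlinearly.

## Known limitations

- Exact solutions require linearity; no nonlinear reaction terms.
- The FD solver is a verification tool: fixed mesh, first-order in time,
  no adaptivity, no higher-order integrator.
- Full-profile evaluation uses double precision; only the boundary
  colonization test is hardened against deep-tail cancellation. Front
  positions in a deep tail under strong production inherit ~1e−16·e^{kt}
  absolute noise.
- Custom growth laws are trusted to be positive and non-decreasing; only
  L(0) consistency is validated.
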