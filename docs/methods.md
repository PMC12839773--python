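# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `flatpath`, at the level a maintainer or reviewer needs
to judge what the tests do and do not establish.

## Fluctuation model: periodic smooth random functions

Fluctuations are L-periodic band-limited Gaussian trigonometric sums

ζ(t) = α (a₀ + Σ_{j=1}^{r} aⱼ cos(2πjt/L) + bⱼ sin(2πjt/L)),  r = ⌊L/λ⌋,

with wavelength λ controlling the band limit 2π/λ. Being trigonometric
polynomials they are entire: the package differentiates and integrates them
term by term in closed form, which is what makes pathwise (random-ODE)
control synthesis exact — a controller that needs ζ̈ receives the true
value, not a finite difference.

**Standard normalisation.** All 2r+1 coefficients are i.i.d. N(0, 1/(2r+1)),
drawn in the fixed order (a₀, a₁, b₁, …, a_r, b_r) from
`numpy.random.default_rng(seed)`; one integer seed per function, no global
state. The pointwise variance is α²(r+1)/(2r+1) → α²/2 and
E[ζ̇²] = α² Σⱼ (2πj/L)²/(2r+1), both verified by Monte Carlo in the suite.

**Big normalisation.** The package uses the real-coefficient scaling
a₀ ~ N(0, 2/((2r+1)λ)), aⱼ, bⱼ ~ N(0, 4/((2r+1)λ)) (j ≥ 1), i.e. the
standard real trigonometric normalisation of smooth random functions with
the variance multiplied by 2/λ. A closed-form Fourier computation
(Σ_{j≥1}(1 − cos jθ)/j² = πθ/2 − θ²/4) gives

Var[∫₀ᵗ ζ] = 2Lt/((2r+1)λ) → t  for 0 < t < L as λ → 0,

so indefinite integrals converge to standard Brownian paths — the property
the "big" regime exists for. A uniform per-coefficient variance
2/((2r+1)λ) (one reading of the source text) would instead give
Var[∫₀¹ζ] = (L+1)/(2L) ≈ 0.56 at L = 8 and was rejected on that ground;
the suite checks Var[∫₀ᵗζ] against t within 10% at λ = 0.01 for
t ∈ {0.5, 1}.

**Tube bound.** P(sup_{[0,T]} ζ ≥ u) is bounded by the time-zero Gaussian
tail (Mills ratio) plus the expected Rice up-crossing count, sharing the
Gaussian factor:

exp(−u²/(2σ²)) · (σ/(√(2π)u) + Tλ₂/(2πσ)),  σ² = E[ζ²], λ₂² = E[ζ̇²],

clipped to [0, 1] since it reports a probability. The exact placement of
the factors differs between renderings of this classical bound; the
implemented form is validated *only as an upper bound*, by Monte Carlo
domination (5,000 paths, thresholds 1–2, 2 MC standard errors of slack).

## Symbolic models and jets

`ControlAffineModel` stores states, inputs, fluctuation base names, drift
f, input gain G, additive noise N, outputs h and a parameter table. Drift
and gain may reference fluctuation jets (the oculomotor model has ζ_X inside
its kinematic nonlinearity); setting every jet to zero always yields the
mean model. Formal derivatives are plain symbols `name_d1`, `name_d2`, …,
canonicalised so the derivative of `zeta_d1` is `zeta_d2`. Numeric binding
maps each base name to a signal object with `evaluate(t, order)` — a smooth
random function or a symbolic (deterministic) signal such as the meal input.

## Flatness certification and parametrisation

The dynamical extension algorithm is implemented for static-feedback-
linearisable control-affine systems, the class containing every worked
example; a candidate whose input direction appears but is linearly
dependent on previously gathered ones would need genuine dynamic extension
and is rejected with a diagnostic rather than silently mis-certified.
Candidates are processed in the order given; accumulated input directions
are tracked by the generic rank of the stacked coefficient rows.

Zero- and rank-testing is "generic": symbolic simplification first, then
evaluation at 10 random points (fixed probe seed, points drawn away from
structured values) with 1e-12 relative tolerance; undefined function
applications are masked consistently by structure before numeric probing.
Singular loci of the decoupling matrix are additionally guarded at run
time: every feedback evaluation checks |det A| against 1e-12 and reports
the offending state point.

The functional parametrisation solves the stacked chain map
{ωᵢ^(k) = chainᵢₖ(x, ζ)} for x with `sympy.solve`, then inverts the
decoupling relation for u; `verify_parametrisation` substitutes both back
into the model equations, differentiating the parametrisation with the
shift rules d/dt ω^(k) = ω^(k+1), d/dt ζ^(k) = ζ^(k+1). All engine algebra
stays fully symbolic (parameters included); numbers enter only at
lambdification.

Point-to-point plans use, per component, the unique degree-(2κᵢ−1)
polynomial matching the κᵢ endpoint jets at each end (Hermite conditions
solved on the scaled variable s = (t−t₀)/(t₁−t₀) for conditioning).

## Tracking, simulation, and risk

Default gains place a κ-fold pole at p = 2 (time units⁻¹); any Hurwitz
coefficient row is accepted, anything else rejected. Controllers come in
`oracle` mode (true fluctuation jets substituted — the full-knowledge
assumption made explicit and testable) and `mean` mode (all jet terms
zeroed). Closed loops integrate with fixed-step classical RK4 at
dt = 1e-3 time units by default: the noise is band-limited with λ ≥ 0.1,
so the step resolves all spectral content; the suite checks 4th-order
convergence under step halving. Traces are bit-reproducible given seed and
step.

Discrepancies follow the active-inference reading: ε_act = ω − ω_r (risk)
and ε_obs = y − ŷ with ŷ the mean-observation prediction. The risk proxy is
the equal-covariance Gaussian Kullback–Leibler divergence integrated along
the path, ∫ ½ ε_actᵀ Π ε_act dt (trapezoid rule, Π symmetric positive
definite, identity by default). The correspondence with the pathwise
divergence between anticipated and goal-conditioned outcome densities is
asserted only as an *ordering* property — tracking < open loop
(< zero action where the uncontrolled plant stays finite) on paired runs —
not as an equality.

Decay rates are estimated by a log-linear fit of ‖ε_act‖ over the
[0.2, 0.8] fraction of the run (tests widen this to [0.5, 0.95] where
needed), truncated at the 1e-12 noise floor. With a κ-fold pole the
envelope is (1 + pt + …)e^(−pt), so fits only approach p for pt ≫ 1; test
horizons are chosen accordingly.

## Oculomotor example

Parameters: eye inertia Ie = 4.032e-7 kg·m² (yaw channel doubled: 2Ie),
screen distance d = 10 m, projection centre at the origin, four noise
channels with L = 8 s, λ = 2 s (r = 4 harmonics each) and amplitude α.
The decoupling matrix is diagonal with entries δ_X/(2dIe), δ_Y/(dIe),
δ = d² + (pos − centre)² ≥ d² > 0: no singular locus anywhere, asserted
along every simulated path. δ is the *squared* distance factor, fixed by
re-deriving the velocity kinematics from X = X₀ + d·tan ψ, where the factor
(d² + (X−X₀−ζ_X)²)/d is unambiguous. All derived expressions (decoupling,
feedback, open-loop torques) are regenerated symbolically from the model;
no printed intermediate form is trusted.

Figure-style runs start exactly on the reference jets (offset starts are
reserved for decay tests). Spans: sigmoid on [0, 80] s; quatrefoil on one
period [0, 2π]; hypocycloid on its closing period [0, 6π] (least common
period of the two angular arguments). The Y-channel sigmoid reuses the same
tanh family with a later, lower rise (the X-channel parameters are the
stated ones). The screen distance is named `d_screen` to avoid clashing
with the meal decay rate `d_meal` of the Bergman model; the tube threshold
is `u_thr` and the wavelength `lambda_w` throughout.

## Delays and predictors

Histories are uniform buffers with linear interpolation at the simulation
step. The integral predictor solves
p(t) = x(t) + ∫_{t−τ}^{t} f(p(ξ), u(ξ)) dξ by Picard iteration with
trapezoidal quadrature (default step τ/200, tolerance 1e-10, cap 100,
warm-started from the previous window); divergence is reported, never
truncated. p(t) approximates x(t+τ) because the input that will act on the
plant during [t, t+τ] is exactly the already-commanded history on
[t−τ, t]. The delayed observer x̂̇ = f(x̂, u) + K(x(t) − x̂(t−τ)) exposes K as
a free parameter — no stability certificate for K is computed; convergence
is verified empirically per run. The stabilising map applied to the
predicted state is the flatness-based tracking controller of the undelayed
model, evaluated at the advanced time; fluctuation-advance terms (ζ at
t+τ) exist only in oracle mode.

## Generalised coordinates

The linearised differentiation d1 obeys the product/chain rule and deletes
every monomial containing two or more derivative factors counted with
multiplicity (X′G′ dies; (k1+X)G″ and X²G′ survive). This is the operative
rule behind the local linear approximation d^k/dt^k F(ξ) = ∇F(ξ)·ξ^(k);
a stricter literal reading that also deletes single-derivative terms with
state cofactors is inconsistent with that approximation and with the
glucose computation, and was therefore not adopted. Primes denote
linearised derivatives, dots full ones; comparisons map primes to dots
before subtracting. Higher-order truncations d_k are representable but only
d1 is exercised.

The Bergman minimal model ships with synthetic rate constants of
literature-plausible magnitude (k₁ = k₂ = 0.05, k₃ = 5e-4, k₄ = 0.2 per
minute; basal glucose 90 mg/dL, basal insulin 10 mU/L; meal amplitude 30,
stiffness 0.5/min, bolus at t = 40 min, decay 0.05/min) — no numeric values
are printed in the source literature, so these were chosen once so that a
meal visibly excites the X′G′ cross term; all are overridable. The paired
demonstration tracks a postprandial excursion reference (a Gaussian bump of
40 mg/dL overlapping the meal): with a constant reference and exact
tracking Ġ ≡ 0 and the two laws coincide, so a moving reference is what
makes the failure observable. Steady-window RMS is taken over the final
60% of the run.

## What the synthetic conditions do and do not show

All experiments run on the package's own generative models with the
band-limited noise above — there is no external data. Passing tests
establish internal mathematical consistency (exactness of the calculus,
the certified algebraic identities, convergence orders, bound domination,
the predicted qualitative orderings) under smooth, band-limited, Gaussian,
full-state-measurable conditions. They do not speak to unmodelled dynamics,
rough (non-differentiable) noise, partial observation or parameter
mismatch: observers/estimators, robust and model-free control are
explicitly out of scope. Reported problem sizes (runs of 2π–120 time
units at dt = 1e-3–1e-2, 2,000–20,000 Monte Carlo draws) are the package's
chosen defaults and are stated alongside each test.

## Numerical conventions

* Probe points for generic zero/rank tests: uniform on [0.37, 1.83], fixed
  seed, 10 points, 1e-12 relative tolerance.
* RK4 everywhere, fixed step; delayed terms interpolate frozen histories,
  which is consistent because τ > dt in all shipped configurations.
* Seeds: one integer per smooth random function; multi-channel experiments
  derive per-channel seeds from the master seed via
  `numpy.random.SeedSequence`, reduced mod 2³¹.
* Degenerate inputs rejected with explanatory errors: non-positive periods,
  wavelengths, poles, tolerances; non-Hurwitz gain rows; non-SPD precision
  matrices; non-increasing time grids; singular decoupling evaluations.
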