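# flatpath

Differential-flatness control synthesis under smooth random fluctuations,
for generative models of biological motor control.

Active-inference accounts of behaviour ask how an agent turns a desired
sensory trajectory into the actions that realise it. For a *differentially
flat* generative model the answer is closed-form: there is a flat output
ω such that every state and action is a function of ω and finitely many of
its time derivatives — no differential equation need be integrated. This
package implements that programme pathwise, with the fluctuations modelled
as band-limited periodic Gaussian trigonometric sums (smooth random
functions), so that every formal derivative of the noise is available
exactly and control laws can be evaluated sample path by sample path.

It is aimed at computational-neuroscience and control researchers who want
to build, certify and simulate small symbolic stochastic models: oculomotor
pursuit, glucose–insulin regulation, delayed sensorimotor loops.

## The core objects

For a control-affine stochastic model

    dx/dt = f(x, ζ) + G(x, ζ) u + N(ζ),      y = h(x, ζ),

with smooth exogenous fluctuations ζ, the package provides:

* **Smooth random functions** (`smooth_random`) — L-periodic sums
  ζ(t) = α (a₀ + Σⱼ aⱼ cos(2πjt/L) + bⱼ sin(2πjt/L)), r = ⌊L/λ⌋ harmonics,
  coefficients i.i.d. N(0, 1/(2r+1)); exact derivatives/antiderivatives of
  every order; a "big" normalisation whose indefinite integrals converge to
  standard Brownian paths as λ → 0; and the Mills + Rice tube bound
  P(sup ζ ≥ u) ≤ exp(−u²/2σ²)(σ/(√(2π)u) + Tλ₂/(2πσ)).
* **Flatness engine** (`flat_core`) — the dynamical extension algorithm:
  differentiate each candidate ωᵢ along the flow until an independent input
  direction appears (Brunovský index κᵢ); the tuple is flat iff Σκᵢ = n and
  the decoupling matrix A(x, ζ) is generically invertible. From a
  certificate it derives the functional parametrisation x = A(ω-jet, ζ-jet),
  u = B(ω-jet, ζ-jet), verifies it by substitution, builds the linearising
  feedback u = A⁻¹(v − b), a Brunovský chain realisation, and polynomial
  point-to-point plans (Hermite interpolation of endpoint jets).
* **Tracking** (`tracking`) — vᵢ = ω_{r,i}^(κᵢ) − Σⱼ λᵢⱼ(ωᵢ^(j) − ω_{r,i}^(j))
  with κ-fold-pole Hurwitz gains, giving error dynamics
  e^(κ) + Σ λⱼ e^(j) = 0; oracle (full noise knowledge) and mean
  (noise-blind) controller modes; fixed-step RK4 pathwise simulation; and
  active-inference discrepancy metrics ε_act = ω − ω_r, ε_obs = y − ŷ with a
  Gaussian risk proxy ∫ ½ ε_actᵀ Π ε_act dt.
* **Oculomotor example** (`oculomotor`) — eye/screen model with Listing-law
  kinematics, flat output (X, Y), κ = (2, 2); sigmoid, quatrefoil and
  hypocycloid references; open-loop and closed-loop experiments.
* **Delays** (`delay_predict`) — δ-flat parametrisation of the
  input-delayed model (the action carries argument t + τ), a delayed
  observer and a Picard integral predictor, and predictive tracking.
* **Generalised coordinates** (`gencoords`) — the linearised differentiation
  d1 (truncating products of derivative factors) and the Bergman
  glucose–insulin demonstration that tracking laws built from it fail
  exactly when the Brunovský index exceeds 2: the third glucose derivative
  loses the cross term −2X′G′.

## Worked example

```python
import flatpath as fp

model = fp.simple_example()                      # x1' = x2 + ζx1, x2' = f + u + ζx2, y = x1 + ζy
cert = fp.brunovsky_analysis(model, [model.outputs[0]])
par = fp.functional_parametrisation(model, cert)
print(cert.kappas, cert.flat)
for x, e in zip(model.states, par.x_exprs):
    print(x, "=", e)
print("u =", par.u_exprs[0])
```

prints

```
(2,) True
x1 = omega1 - zeta_y
x2 = omega1_d1 - zeta_x1 - zeta_y_d1
u = omega1_d2 - zeta_x1_d1 - zeta_x2 - zeta_y_d2 - f(omega1 - zeta_y, omega1_d1 - zeta_x1 - zeta_y_d1)
```

i.e. the sensed output y certifies as a flat output with index 2, and the
action is the inverse sensory-to-motor map: the second derivative of the
goal minus the internal force and every fluctuation influence —
`verify_parametrisation` confirms the substitution leaves zero residuals.

Closing the loop on the oculomotor model (`examples/oculomotor_tracking.py`):

```
fluctuation channels: 4, harmonics per channel r = 4
RMS action discrepancy  ||eps_act|| = 1.304e-06 m
max action discrepancy             = 2.759e-06 m
```

with four noise channels at amplitude 1e-5 the eye tracks the quatrefoil
target to micrometre-scale discrepancy — reference and actual curves
coincide visually.

Each script in `examples/` exercises one capability (noise statistics and
the tube bound, certification, oculomotor tracking, delayed tracking, the
generalised-coordinate comparison) and prints what the numbers mean.

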