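"""Sample a periodic smooth random function and characterise it.

Draws a band-limited Gaussian trigonometric sum, shows its exact calculus,
the Brownian behaviour of big-mode integrals, and the tube-exceedance bound
against a Monte Carlo estimate.
"""

import numpy as np

import flatpath as fp

f = fp.sample_srf(L=8.0, lambda_w=2.0, alpha=1.0, seed=7)
print(f"harmonics r = {f.r} (period 8, wavelength 2 -> 2r+1 = {2*f.r+1} coefficients)")
print(f"zeta(1.0) = {f.evaluate(1.0):+.6f},  zeta'(1.0) = {f.evaluate(1.0, 1):+.6f}")
print(f"periodicity check |zeta(t+L)-zeta(t)| = {abs(f.evaluate(9.0)-f.evaluate(1.0)):.2e}")

big = [fp.sample_srf(8.0, 0.01, mode="big", seed=s).integral(1.0) for s in range(2000)]
print(f"big mode: Var[int_0^1 zeta] = {np.var(big):.3f} (Brownian limit: 1.0)")

sigma, lam2 = fp.pointwise_std(8, 2), fp.derivative_rms(8, 2)
t = np.linspace(0, 8, 1600, endpoint=False)
sups = [fp.sample_srf(8, 2, seed=s).evaluate(t).max() for s in range(2000)]
for u in (1.0, 1.5, 2.0):
    bound = fp.tube_exceedance_bound(
        fp.TubeBoundInputs(sigma=sigma, lambda2=lam2, u_thr=u, horizon=8.0))
    emp = float(np.mean(np.asarray(sups) >= u))
    print(f"P(sup zeta >= {u:.1f}) over one period: empirical {emp:.3f} <= bound {bound:.3f}")
print("the Mills + Rice bound dominates the empirical exceedance at every threshold")
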