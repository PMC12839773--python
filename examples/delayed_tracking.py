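"""Tracking through an input delay with state prediction.

The plant's action acts with delay tau = 0.2 s.  The integral predictor
solves the implicit window relation for x(t + tau); the tracking law is then
evaluated at the advanced time on the predicted state.
"""

import numpy as np
import sympy as sp

import flatpath as fp
from flatpath import delay_predict as dp

x1, x2 = sp.symbols("x1 x2")
model = fp.simple_example(f_expr=-sp.sin(x1) - x2, stochastic=False)
cert = fp.brunovsky_analysis(model, [x1])
t = sp.Symbol("t")
ref = fp.ReferenceTrajectory([1 + sp.sin(t) / 2], t, max_order=2,
                             domain=(0, 12), name="sine")
gains = fp.TrackingGains.pole_placement(cert.kappas, pole=2.0)
controller = fp.tracking_controller(model, cert, ref, gains, mode="mean")

tau = 0.2
delayed = dp.DelayedModel(model, tau)

# predictor accuracy on a pure decay (closed-form flow e^{a tau} x)
a = -0.7
lin = fp.ControlAffineModel(states=(x1,), inputs=(sp.Symbol("u"),),
                            drift=(a * x1,), input_gain=sp.Matrix([[1]]))
pred, info = dp.integral_predictor(
    dp.DelayedModel(lin, tau), dp.PredictorConfig(quad_step=tau / 200),
    lambda s: np.array([2.0 * np.exp(a * s)]), lambda s: np.array([0.0]), 0.0)
print(f"integral predictor vs exact flow: |error| = "
      f"{abs(pred[0] - 2*np.exp(a*tau)):.2e} in {info['iterations']} iterations")

trace = dp.simulate_predictive_tracking(
    delayed, controller, x0=[0.5, 0.0], t_span=(0, 12), dt=2e-3,
    predictor=dp.PredictorConfig(kind="integral", quad_step=tau / 100))
print(f"predictive tracking, tau = {tau}: terminal |eps_act| = "
      f"{np.abs(trace.eps_act[-1]).max():.2e}")
print("prediction restores the undelayed closed-loop behaviour: the delayed "
      "plant still converges onto the moving reference")
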