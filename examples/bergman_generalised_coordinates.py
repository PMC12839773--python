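"""When generalised coordinates fail: glucose tracking under a meal.

The glucose output of the minimal glucose-insulin model has Brunovsky index
3.  The linearised (generalised-coordinate) third derivative misses the
cross term -2 X'G'; the tracking law built from it is steered by that term
whenever a meal excites the insulin compartment, while the flatness-based
law cancels it exactly.
"""

import numpy as np

from flatpath import gencoords as gc

run = gc.bergman_demo()
print(f"symbolic gap (full - linearised third derivative): {run.missing_term}")
print(f"steady-window RMS glucose error, flatness-based law:        "
      f"{run.steady_rms_flat:.2e} mg/dL")
print(f"steady-window RMS glucose error, generalised-coordinate law: "
      f"{run.steady_rms_gc:.2e} mg/dL")
print(f"peak driving term |-2 X'G'| along the run: "
      f"{np.abs(run.driving_term).max():.2e}")

calm = gc.bergman_demo(meal=False, t_span=(0.0, 60.0))
print(f"without a meal (X'G' = 0) both laws agree: flat "
      f"{calm.steady_rms_flat:.1e}, gen-coord {calm.steady_rms_gc:.1e}")
print("components with index <= 2 (cruise control, oculomotor channels) are "
      "unaffected; the failure is specific to index >= 3")
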