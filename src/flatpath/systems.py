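"""Small benchmark models used across the package and its tests."""

from __future__ import annotations

import sympy as sp

from .model import ControlAffineModel

__all__ = ["double_integrator", "simple_example"]


def double_integrator() -> ControlAffineModel:
    """x1' = x2, x2' = u, y = x1 — the elementary flat system."""
    x1, x2, u = sp.symbols("x1 x2 u")
    return ControlAffineModel(
        states=(x1, x2),
        inputs=(u,),
        drift=(x2, 0),
        input_gain=sp.Matrix([[0], [1]]),
        outputs=(x1,),
        name="double_integrator",
    )


def simple_example(f_expr=None, stochastic: bool = True) -> ControlAffineModel:
    """Scalar-action Newton-type model

        x1' = x2 + zeta_x1,  x2' = f(x1, x2) + u + zeta_x2,  y = x1 + zeta_y.

    ``f_expr`` is an expression in the symbols x1, x2 (default: an undefined
    symbolic function f(x1, x2), which keeps the flatness algebra fully
    generic).  ``stochastic=False`` drops the fluctuation channels.
    """
    x1, x2, u = sp.symbols("x1 x2 u")
    if f_expr is None:
        f_expr = sp.Function("f")(x1, x2)
    else:
        f_expr = sp.sympify(f_expr)
    if stochastic:
        zx1, zx2 = sp.Symbol("zeta_x1"), sp.Symbol("zeta_x2")
        zy = sp.Symbol("zeta_y")
        return ControlAffineModel(
            states=(x1, x2),
            inputs=(u,),
            fluctuations=("zeta_x1", "zeta_x2", "zeta_y"),
            drift=(x2, f_expr),
            input_gain=sp.Matrix([[0], [1]]),
            noise=(zx1, zx2),
            outputs=(x1 + zy,),
            name="simple_example",
        )
    return ControlAffineModel(
        states=(x1, x2),
        inputs=(u,),
        drift=(x2, f_expr),
        input_gain=sp.Matrix([[0], [1]]),
        outputs=(x1,),
        name="simple_example_mean",
    )
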