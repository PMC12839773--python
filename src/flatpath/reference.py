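"""Reference trajectories with exact derivatives.

A reference is a vector-valued function of time whose derivatives up to a
stated maximal order are available in closed form (built from sympy
expressions, so differentiation is exact, not numerical).
"""

from __future__ import annotations

import numpy as np
import sympy as sp

__all__ = ["ReferenceTrajectory"]


class ReferenceTrajectory:
    """Goal path t -> R^m with derivatives to ``max_order``."""

    def __init__(self, exprs, t: sp.Symbol, max_order: int = 2,
                 domain=(0.0, 1.0), name: str = "reference"):
        self.t_symbol = t
        self.exprs = tuple(sp.sympify(e) for e in exprs)
        self.m = len(self.exprs)
        self.max_order = int(max_order)
        self.domain = (float(domain[0]), float(domain[1]))
        self.name = name
        self._fns = []
        for e in self.exprs:
            per_order = []
            d = e
            for _ in range(self.max_order + 1):
                per_order.append(sp.lambdify(t, d, "numpy"))
                d = sp.diff(d, t)
            self._fns.append(per_order)

    @classmethod
    def constant(cls, values, max_order: int = 2, domain=(0.0, 1.0),
                 name: str = "constant") -> "ReferenceTrajectory":
        t = sp.Symbol("t")
        return cls([sp.Float(v) for v in np.atleast_1d(values)], t,
                   max_order=max_order, domain=domain, name=name)

    def value(self, t, order: int = 0) -> np.ndarray:
        """Component values of the order-th derivative at time t."""
        if order > self.max_order:
            raise ValueError(
                f"reference {self.name!r} differentiable only to order {self.max_order}"
            )
        tt = np.asarray(t, dtype=float)
        return np.array(
            [np.broadcast_to(f[order](tt), tt.shape) if tt.ndim else float(f[order](tt))
             for f in self._fns]
        )

    def jets(self, t: float, max_order: int) -> np.ndarray:
        """(m, max_order+1) array of derivatives 0..max_order at time t."""
        return np.array(
            [[float(self._fns[i][k](t)) for k in range(max_order + 1)]
             for i in range(self.m)]
        )

    def __repr__(self) -> str:
        return (f"ReferenceTrajectory({self.name!r}, m={self.m}, "
                f"max_order={self.max_order}, domain={self.domain})")
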