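"""Symbolic control-affine generative models with smooth exogenous fluctuations.

A model is

    dx/dt = f(x, zeta-jet) + G(x, zeta-jet) u + N(zeta-jet)
    y     = h(x, zeta-jet)

where the fluctuation symbols ``zeta`` are exogenous smooth signals carrying
formal derivatives of every order (their "jet").  Setting every jet symbol to
zero yields the mean (deterministic) model.  Jets are plain sympy symbols with
the naming convention ``name`` (order 0), ``name_d1``, ``name_d2``, ...

Numeric binding maps each fluctuation base name to an exogenous signal object
exposing ``evaluate(t, order)`` — typically a
:class:`~flatpath.smooth_random.SmoothRandomFunction` or a
:class:`SymbolicSignal` — so every formal derivative is evaluated exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "jet_symbol",
    "jet_order",
    "ControlAffineModel",
    "SymbolicSignal",
    "NoiseBinding",
]

_JET_RE = re.compile(r"^(?P<base>.+?)_d(?P<order>[1-9][0-9]*)$")


def jet_symbol(base: str, order: int = 0) -> sp.Symbol:
    """Formal derivative symbol of ``base`` of the given order.

    Canonical: if ``base`` is itself a jet name (``name_dk``) the orders are
    combined, so the derivative of ``zeta_d1`` is ``zeta_d2``, never
    ``zeta_d1_d1``.
    """
    if order < 0:
        raise ValueError("jet order must be >= 0")
    m = _JET_RE.match(base)
    if m:
        base, order = m.group("base"), order + int(m.group("order"))
    return sp.Symbol(base if order == 0 else f"{base}_d{order}")


def jet_order(symbol: sp.Symbol) -> tuple[str, int]:
    """Inverse of :func:`jet_symbol`: (base name, derivative order)."""
    m = _JET_RE.match(symbol.name)
    if m:
        return m.group("base"), int(m.group("order"))
    return symbol.name, 0


def _as_exprs(exprs) -> tuple[sp.Expr, ...]:
    return tuple(sp.sympify(e) for e in exprs)


@dataclass(frozen=True)
class ControlAffineModel:
    """Stochastic generative model, affine in the action.

    Parameters
    ----------
    states, inputs : sympy symbols.
    fluctuations : base names of the exogenous smooth signals.
    drift : n expressions f_i(x, zeta-jet, theta).
    input_gain : n x m matrix G(x, zeta-jet, theta).
    noise : n additive expressions N_i(zeta-jet); zero if omitted.
    outputs : p expressions h(x, zeta-jet, theta).
    params : mapping parameter symbol -> numeric value (or symbol).
    """

    states: tuple[sp.Symbol, ...]
    inputs: tuple[sp.Symbol, ...]
    fluctuations: tuple[str, ...] = ()
    drift: tuple[sp.Expr, ...] = ()
    input_gain: sp.Matrix = None
    noise: tuple[sp.Expr, ...] = ()
    outputs: tuple[sp.Expr, ...] = ()
    params: dict = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(sp.Symbol(s) if isinstance(s, str) else s for s in self.states))
        object.__setattr__(self, "inputs", tuple(sp.Symbol(s) if isinstance(s, str) else s for s in self.inputs))
        object.__setattr__(self, "fluctuations", tuple(str(z) for z in self.fluctuations))
        object.__setattr__(self, "drift", _as_exprs(self.drift))
        gain = self.input_gain
        if gain is None:
            gain = sp.zeros(self.n, self.m)
        object.__setattr__(self, "input_gain", sp.Matrix(gain))
        noise = _as_exprs(self.noise) if self.noise else tuple(sp.S.Zero for _ in self.states)
        object.__setattr__(self, "noise", noise)
        object.__setattr__(self, "outputs", _as_exprs(self.outputs))
        object.__setattr__(self, "params", dict(self.params))
        if len(self.drift) != self.n or len(noise) != self.n:
            raise ValueError("drift/noise must have one expression per state")
        if self.input_gain.shape != (self.n, self.m):
            raise ValueError(
                f"input gain must be {self.n}x{self.m}, got {self.input_gain.shape}"
            )
        declared = set(self.states) | set(self.inputs) | set(self.params)
        for e in (*self.drift, *self.input_gain, *self.noise, *self.outputs):
            for s in sp.sympify(e).free_symbols:
                base, _ = jet_order(s)
                if s not in declared and base not in self.fluctuations:
                    raise ValueError(f"expression references undeclared symbol {s}")

    # -- basic structure ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def m(self) -> int:
        return len(self.inputs)

    def rhs(self, with_params: bool = True) -> tuple[sp.Expr, ...]:
        """dx/dt = f + G u + N, one expression per state."""
        u = sp.Matrix(self.inputs)
        gu = self.input_gain * u if self.m else sp.zeros(self.n, 1)
        out = tuple(
            sp.expand(self.drift[i] + gu[i] + self.noise[i]) for i in range(self.n)
        )
        if with_params:
            out = tuple(e.subs(self.params) for e in out)
        return out

    # -- fluctuation jets --------------------------------------------------
    def zeta_jets_in(self, expr: sp.Expr) -> list[sp.Symbol]:
        """Fluctuation-jet symbols appearing in ``expr``, sorted (base, order)."""
        jets = []
        for s in sp.sympify(expr).free_symbols:
            base, order = jet_order(s)
            if base in self.fluctuations:
                jets.append((self.fluctuations.index(base), order, s))
        return [s for *_key, s in sorted(jets, key=lambda x: (x[0], x[1]))]

    def zero_noise_subs(self, exprs: Iterable[sp.Expr]) -> dict:
        subs = {}
        for e in exprs:
            for s in self.zeta_jets_in(e):
                subs[s] = 0
        return subs

    def mean(self) -> "ControlAffineModel":
        """The mean generative model: every fluctuation jet set to zero."""
        all_exprs = (*self.drift, *self.input_gain, *self.noise, *self.outputs)
        subs = self.zero_noise_subs(all_exprs)
        return ControlAffineModel(
            states=self.states,
            inputs=self.inputs,
            fluctuations=(),
            drift=tuple(e.subs(subs) for e in self.drift),
            input_gain=self.input_gain.subs(subs),
            noise=tuple(e.subs(subs) for e in self.noise),
            outputs=tuple(e.subs(subs) for e in self.outputs),
            params=self.params,
            name=self.name + "_mean",
        )

    # -- calculus ----------------------------------------------------------
    def total_derivative(self, expr: sp.Expr, input_jets: bool = False) -> sp.Expr:
        """Total time derivative of ``expr`` along the model flow.

        State symbols differentiate to the full right-hand side (so inputs
        appear), fluctuation jets shift up one order.  With ``input_jets``,
        input symbols are treated as time functions too (u -> u_d1, ...);
        otherwise an input already present in ``expr`` raises, since chain
        construction in the flatness engine must stop before that point.
        """
        expr = sp.sympify(expr)
        rhs = self.rhs(with_params=False)
        out = sp.S.Zero
        for xi, fi in zip(self.states, rhs):
            out += sp.diff(expr, xi) * fi
        for s in expr.free_symbols:
            base, order = jet_order(s)
            if base in self.fluctuations:
                out += sp.diff(expr, s) * jet_symbol(base, order + 1)
            elif any(base == u.name for u in self.inputs) and s not in self.states:
                if not input_jets:
                    if s in self.inputs:
                        raise ValueError(
                            "expression contains an input symbol; pass input_jets=True"
                        )
                else:
                    out += sp.diff(expr, s) * jet_symbol(base, order + 1)
        return sp.expand(out)

    def subs_params(self, expr):
        return sp.sympify(expr).subs(self.params)


class SymbolicSignal:
    """Deterministic exogenous signal defined by a sympy expression in time.

    Provides the same ``evaluate(t, order)`` interface as a smooth random
    function, with exact symbolic derivatives.
    """

    def __init__(self, expr: sp.Expr, t: sp.Symbol, max_order: int = 4):
        self._t = t
        self._fns = []
        e = sp.sympify(expr)
        for _ in range(max_order + 1):
            self._fns.append(sp.lambdify(t, e, "numpy"))
            e = sp.diff(e, t)
        self.max_order = max_order

    def evaluate(self, t, order: int = 0):
        if order > self.max_order:
            raise ValueError(f"signal only differentiable to order {self.max_order}")
        out = np.asarray(self._fns[order](np.asarray(t, dtype=float)), dtype=float)
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate


class _ZeroSignal:
    def evaluate(self, t, order: int = 0):
        return np.zeros_like(np.asarray(t, dtype=float)) + 0.0

    __call__ = evaluate


class NoiseBinding:
    """Maps fluctuation base names to exogenous signal objects."""

    def __init__(self, signals: Mapping[str, object] | None = None):
        self.signals = dict(signals or {})

    @classmethod
    def zero(cls, names: Sequence[str]) -> "NoiseBinding":
        return cls({n: _ZeroSignal() for n in names})

    def jets(self, t: float, specs: Sequence[tuple[str, int]]) -> dict:
        """Values of the requested (base, order) jets at time t."""
        out = {}
        for base, order in specs:
            if base not in self.signals:
                raise KeyError(f"no signal bound for fluctuation {base!r}")
            out[(base, order)] = float(self.signals[base].evaluate(t, order))
        return out

    def vector(self, t: float, specs: Sequence[tuple[str, int]]) -> np.ndarray:
        return np.array(
            [self.signals[b].evaluate(t, k) for b, k in specs], dtype=float
        )
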