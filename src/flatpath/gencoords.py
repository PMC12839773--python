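"""Generalised coordinates of motion: linearised differentiation and its limits.

The linearised (first-order) differentiation d1 follows the product/chain
rule but truncates every monomial containing two or more derivative factors
(counting multiplicity).  Repeated application realises the local linear
approximation d^k/dt^k F(xi) = grad F(xi) . xi^(k): cross terms such as
X'G' are discarded while terms linear in a single derivative of any order
(e.g. (k1+X) G'') survive.

Convention: primes (symbols ``name_p1``, ``name_p2``, ...) denote linearised
derivatives; dots (``name_d1``, ...) full derivatives.  Comparisons map
primes to dots before subtracting.

The Bergman minimal glucose-insulin model demonstrates when this matters:
the glucose output has Brunovsky index 3, and the linearised third derivative
misses exactly the cross term -2 X' G'.  A tracking law built from it leaves
an error dynamics steered by -2 X' G', which does not vanish whenever a meal
excites the insulin compartment; the flatness-based law (full differentiation)
cancels it.  Components with index <= 2 (the car's cruise control, the
oculomotor channels) are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from . import flat_core, tracking
from .model import ControlAffineModel, NoiseBinding, SymbolicSignal, jet_symbol, jet_order
from .reference import ReferenceTrajectory

__all__ = [
    "prime_symbol",
    "d1",
    "dt_formal",
    "primes_to_dots",
    "is_first_order",
    "lin_derivative_chain",
    "LinChainReport",
    "gc_derivative_expr",
    "BergmanParams",
    "build_bergman",
    "meal_signal",
    "build_car",
    "bergman_demo",
    "BergmanComparison",
]

_PRIME = "_p"


def prime_symbol(base: str, order: int = 0) -> sp.Symbol:
    """Linearised-derivative (prime) symbol of ``base``."""
    return sp.Symbol(base if order == 0 else f"{base}{_PRIME}{order}")


def _prime_order(s: sp.Symbol) -> tuple[str, int]:
    """(base, order) of a prime symbol; dot-jet symbols (exogenous signals
    already differentiated in a model expression) parse as derivative symbols
    too, so d1 keeps differentiating them."""
    name = s.name
    if _PRIME in name:
        base, _, tail = name.rpartition(_PRIME)
        if tail.isdigit():
            inner, k = jet_order(sp.Symbol(base))
            return inner, k + int(tail)
    return jet_order(s)


def _formal_derivative(expr: sp.Expr, variables, naming) -> sp.Expr:
    """Chain-rule derivative treating every jet symbol of ``variables`` as a
    time function; ``naming(base, order)`` builds the next-order symbol."""
    expr = sp.sympify(expr)
    bases = {str(v) for v in variables}
    out = sp.S.Zero
    for s in expr.free_symbols:
        base, order = naming.order_of(s)
        if base in bases:
            out += sp.diff(expr, s) * naming.symbol(base, order + 1)
    return sp.expand(out)


class _DotNaming:
    @staticmethod
    def symbol(base, order):
        return jet_symbol(base, order)

    @staticmethod
    def order_of(s):
        return jet_order(s)


class _PrimeNaming:
    @staticmethod
    def symbol(base, order):
        return prime_symbol(base, order)

    @staticmethod
    def order_of(s):
        return _prime_order(s)


def dt_formal(expr, variables) -> sp.Expr:
    """Formal full time derivative on dot-jet symbols (no truncation)."""
    return _formal_derivative(expr, variables, _DotNaming)


def _derivative_degree(term: sp.Expr, order_of) -> int:
    """Number of derivative factors in a monomial, counted with multiplicity."""
    deg = 0
    for factor, exponent in term.as_powers_dict().items():
        if factor.is_Symbol:
            _, order = order_of(factor)
            if order > 0:
                deg += int(exponent) if exponent.is_Integer else 2
    return deg


def d1(expr, variables) -> sp.Expr:
    """Linearised differentiation: chain rule on prime symbols, then deletion
    of every monomial with two or more derivative factors."""
    raw = _formal_derivative(expr, variables, _PrimeNaming)
    return _truncate_first_order(raw)


def _truncate_first_order(expr: sp.Expr) -> sp.Expr:
    expr = sp.expand(expr)
    terms = expr.as_ordered_terms() if expr.is_Add else [expr]
    kept = [t for t in terms if _derivative_degree(t, _prime_order) <= 1]
    return sp.Add(*kept)


def is_first_order(expr) -> bool:
    """Structural check of the truncation invariant: every monomial carries
    at most one derivative factor (with multiplicity)."""
    expr = sp.expand(sp.sympify(expr))
    terms = expr.as_ordered_terms() if expr.is_Add else [expr]
    return all(_derivative_degree(t, _prime_order) <= 1 for t in terms)


def primes_to_dots(expr) -> sp.Expr:
    expr = sp.sympify(expr)
    subs = {}
    for s in expr.free_symbols:
        base, order = _prime_order(s)
        if order > 0:
            subs[s] = jet_symbol(base, order)
    return expr.subs(subs)


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinChainReport:
    """Full vs linearised derivative chains of a model output.

    ``full[k]`` / ``linearised[k]`` are the k-th derivatives (the model
    equations substituted once, at order 1; higher orders formal), and
    ``difference[k]`` their gap with primes mapped to dots.
    """

    output: sp.Expr
    full: tuple
    linearised: tuple
    difference: tuple


def _seed_first_derivative(model: ControlAffineModel, output: sp.Expr) -> sp.Expr:
    """First time derivative of the output along the model, inputs included."""
    expr = model.subs_params(output)
    rhs = [model.subs_params(e) for e in model.rhs(with_params=True)]
    out = sp.S.Zero
    for xi, fi in zip(model.states, rhs):
        out += sp.diff(expr, xi) * fi
    for s in expr.free_symbols:
        base, order = jet_order(s)
        if base in model.fluctuations:
            out += sp.diff(expr, s) * jet_symbol(base, order + 1)
    return sp.expand(out)


def lin_derivative_chain(model: ControlAffineModel, output, k: int) -> LinChainReport:
    """First k full and k linearised derivatives of an output, plus their
    symbolic differences order by order."""
    if k < 1:
        raise ValueError("need k >= 1")
    output = sp.sympify(output)
    variables = [*(s.name for s in model.states),
                 *(u.name for u in model.inputs), *model.fluctuations]
    seed = _seed_first_derivative(model, output)
    full = [seed]
    lin = [seed]
    for _ in range(k - 1):
        full.append(dt_formal(full[-1], variables))
        lin.append(d1(lin[-1], variables))
    diffs = [sp.expand(f - primes_to_dots(l)) for f, l in zip(full, lin)]
    return LinChainReport(
        output=output, full=tuple(full), linearised=tuple(lin),
        difference=tuple(diffs),
    )


def gc_derivative_expr(model: ControlAffineModel, output, k: int) -> sp.Expr:
    """The generalised-coordinate k-th derivative of an output expressed in
    (states, inputs, fluctuation jets): the formal d1 chain with every state
    prime recursively replaced by the linearised motion of that state."""
    report = lin_derivative_chain(model, output, k)
    expr = report.linearised[-1]
    state_names = {s.name: s for s in model.states}
    rhs = {s.name: model.subs_params(e)
           for s, e in zip(model.states, model.rhs(with_params=True))}
    variables = [*(s.name for s in model.states),
                 *(u.name for u in model.inputs), *model.fluctuations]

    def substitute(e: sp.Expr) -> sp.Expr:
        while True:
            primes = [(s, *_prime_order(s)) for s in e.free_symbols]
            primes = [(s, b, o) for s, b, o in primes if o > 0 and b in state_names]
            if not primes:
                return e
            s, b, o = max(primes, key=lambda p: p[2])
            repl = rhs[b]
            for _ in range(o - 1):
                repl = d1(repl, variables)
            e = sp.expand(e.subs(s, repl))

    expr = substitute(expr)
    # remaining primes belong to inputs/fluctuations: map them to dot jets
    return sp.expand(primes_to_dots(expr))


# ---------------------------------------------------------------------------
# Bergman minimal model and car cruise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BergmanParams:
    """Synthetic rate constants of literature-plausible magnitude (per min);
    glucose in mg/dL, insulin in mU/L.  The meal disturbance is
    D(t) = B/2 (1 + tanh(gamma (t - t_bol))) exp(-d_meal (t - t_bol))."""

    k1: float = 0.05
    k2: float = 0.05
    k3: float = 5e-4
    k4: float = 0.2
    Gb: float = 90.0
    Ib: float = 10.0
    B: float = 30.0
    gamma_meal: float = 0.5
    t_bol: float = 40.0
    d_meal: float = 0.05

    def __post_init__(self) -> None:
        for f in ("k1", "k2", "k3", "k4", "gamma_meal", "d_meal"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def build_bergman(params: BergmanParams | None = None) -> ControlAffineModel:
    """Three-state glucose-insulin model with the meal D treated as a bound
    exogenous smooth signal:

        G' = -k1 (G - Gb) - X G + D
        X' = -k2 X + k3 (I - Ib)
        I' = -k4 (I - Ib) + u
    """
    params = params or BergmanParams()
    G, X, I = sp.symbols("G X I")
    u = sp.Symbol("u")
    k1, k2, k3, k4, Gb, Ib = sp.symbols("k1 k2 k3 k4 Gb Ib")
    D = sp.Symbol("D")
    return ControlAffineModel(
        states=(G, X, I),
        inputs=(u,),
        fluctuations=("D",),
        drift=(-k1 * (G - Gb) - X * G + D, -k2 * X + k3 * (I - Ib),
               -k4 * (I - Ib)),
        input_gain=sp.Matrix([[0], [0], [1]]),
        outputs=(G,),
        params={k1: params.k1, k2: params.k2, k3: params.k3, k4: params.k4,
                Gb: params.Gb, Ib: params.Ib},
        name="bergman",
    )


def meal_signal(params: BergmanParams, max_order: int = 4) -> SymbolicSignal:
    t = sp.Symbol("t")
    p = params
    expr = (p.B / 2) * (1 + sp.tanh(p.gamma_meal * (t - p.t_bol))) \
        * sp.exp(-p.d_meal * (t - p.t_bol))
    return SymbolicSignal(expr, t, max_order=max_order)


def build_car(M: float = 1200.0, r: float = 0.3, drag=None) -> ControlAffineModel:
    """Longitudinal cruise model M Vx' = -F(Vx) + u/r; flat with output Vx,
    index 1.  ``drag`` is an expression in Vx (default quadratic)."""
    Vx = sp.Symbol("Vx")
    u = sp.Symbol("u")
    Ms, rs = sp.symbols("M r_wheel")
    drag = sp.sympify(drag) if drag is not None else sp.Float(0.4) * Vx**2 + 50 * Vx
    return ControlAffineModel(
        states=(Vx,), inputs=(u,),
        drift=(-drag / Ms,),
        input_gain=sp.Matrix([[1 / (Ms * rs)]]),
        outputs=(Vx,),
        params={Ms: M, rs: r},
        name="car",
    )


# ---------------------------------------------------------------------------
# paired tracking comparison
# ---------------------------------------------------------------------------

class _GcController:
    """Tracking law built from the generalised-coordinate (linearised) top
    derivative: v is formed from the true error jets, but u solves
    gc_expr(x, u, D-jets) = v, so the closed-loop error is steered by the
    missing cross term."""

    def __init__(self, model, cert, reference, gains, gc_expr):
        self.model, self.cert = model, cert
        self.reference, self.gains = reference, gains
        self.mode = "gencoords"
        u = model.inputs[0]
        a = sp.expand(gc_expr).coeff(u, 1)
        b = sp.expand(gc_expr - a * u)
        v = sp.Symbol("v1")
        specs = flat_core._jet_specs_in(model, [a, b])
        chain_list = [e for ch in cert.chains for e in ch]
        self.chain_specs = flat_core._jet_specs_in(model, chain_list)
        self.jet_specs = sorted(set(specs) | set(self.chain_specs),
                                key=lambda bk: (model.fluctuations.index(bk[0]), bk[1]))
        syms = [jet_symbol(bb, k) for bb, k in specs]
        self._u_fn = sp.lambdify(list(model.states) + [v] + syms,
                                 model.subs_params((v - b) / a), "numpy")
        self._specs = specs
        csyms = [jet_symbol(bb, k) for bb, k in self.chain_specs]
        self._chain_fn = sp.lambdify(
            list(model.states) + csyms,
            [model.subs_params(e) for e in cert.chains[0]], "numpy")

    def __call__(self, t, x, jets=None):
        cjv = [jets[s] for s in self.chain_specs]
        meas = [np.asarray(self._chain_fn(*x, *cjv), dtype=float)]
        ref = self.reference.jets(t, self.cert.kappas[0])
        v = tracking.tracking_v(meas, ref, self.gains)
        jv = [jets[s] for s in self._specs]
        return np.atleast_1d(self._u_fn(*x, float(v[0]), *jv))


@dataclass(frozen=True)
class BergmanComparison:
    """Paired noise-free runs: flatness-based vs generalised-coordinate law."""

    trace_flat: tracking.SimulationTrace
    trace_gc: tracking.SimulationTrace
    steady_rms_flat: float
    steady_rms_gc: float
    driving_term: np.ndarray  # -2 X' G' along the gc run
    steady_window: tuple
    missing_term: sp.Expr


def bergman_demo(
    params: BergmanParams | None = None,
    reference: ReferenceTrajectory | None = None,
    gains: tracking.TrackingGains | None = None,
    t_span=(0.0, 120.0),
    dt: float = 0.01,
    meal: bool = True,
) -> BergmanComparison:
    """Glucose tracking with the flatness-based law vs the law built from the
    linearised third derivative, at matched gains, on a meal-excited run.

    The report includes steady-window RMS errors and the driving term
    -2 X'(t) G'(t) along the generalised-coordinate run.
    """
    params = params or BergmanParams()
    if not meal:
        params = BergmanParams(**{**params.__dict__, "B": 1e-30})
    model = build_bergman(params)
    cert = flat_core.brunovsky_analysis(model, [model.states[0]])
    if reference is None:
        if meal:
            # postprandial excursion overlapping the meal, so that the
            # reference keeps dG/dt and dX/dt simultaneously nonzero
            t = sp.Symbol("t")
            mid = params.t_bol + 20.0
            expr = params.Gb + 40 * sp.exp(-((t - mid) / 15) ** 2)
            reference = ReferenceTrajectory([expr], t, max_order=3,
                                            domain=t_span, name="excursion")
        else:
            reference = ReferenceTrajectory.constant(
                [params.Gb], max_order=3, domain=t_span, name="basal_glucose")
    gains = gains or tracking.TrackingGains.pole_placement(cert.kappas, pole=0.5)
    binding = NoiseBinding({"D": meal_signal(params)})
    x0 = np.array([float(reference.value(t_span[0])[0]), 0.0, params.Ib])

    flat_ctrl = tracking.tracking_controller(model, cert, reference, gains,
                                             mode="oracle")
    report = lin_derivative_chain(model, model.states[0], cert.kappas[0])
    gc_expr = gc_derivative_expr(model, model.states[0], cert.kappas[0])
    gc_ctrl = _GcController(model, cert, reference, gains, gc_expr)

    tr_flat = tracking.simulate_closed_loop(
        model, flat_ctrl, binding, x0, t_span, dt,
        metadata={"law": "flatness"})
    tr_gc = tracking.simulate_closed_loop(
        model, gc_ctrl, binding, x0, t_span, dt, reference=reference,
        cert=cert, metadata={"law": "gencoords"})

    t = tr_gc.t
    window = (t_span[0] + 0.4 * (t_span[1] - t_span[0]), t_span[1])
    sel = (t >= window[0]) & (t <= window[1])
    rms = lambda tr: float(np.sqrt((tr.eps_act[sel, 0] ** 2).mean()))  # noqa: E731

    # driving term -2 X' G' with the dynamics substituted, along the gc run
    G, X, I = model.states
    rhs = [model.subs_params(e) for e in model.rhs(with_params=True)]
    u = model.inputs[0]
    specs = flat_core._jet_specs_in(model, rhs)
    syms = [jet_symbol(b, k) for b, k in specs]
    dfn = sp.lambdify(list(model.states) + [u] + syms,
                      -2 * rhs[1] * rhs[0], "numpy")
    drive = np.array([
        dfn(*x_, u_, *[binding.jets(t_, specs)[s] for s in specs])
        for t_, x_, u_ in zip(t, tr_gc.x, tr_gc.u[:, 0])
    ])
    return BergmanComparison(
        trace_flat=tr_flat, trace_gc=tr_gc,
        steady_rms_flat=rms(tr_flat), steady_rms_gc=rms(tr_gc),
        driving_term=drive, steady_window=window,
        missing_term=report.difference[-1],
    )
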