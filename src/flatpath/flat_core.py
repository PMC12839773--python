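"""Symbolic flatness engine.

Certifies candidate flat outputs of control-affine models by the dynamical
extension algorithm, and turns a certificate into the objects flatness-based
control is built from:

* the *derivative chains* omega_i, omega_i', ..., omega_i^(kappa_i - 1) as
  functions of state and fluctuation jets;
* the *decoupling matrix* A(x, zeta) and drift terms b(x, zeta) such that
  omega_i^(kappa_i) = b_i + sum_j A_ij u_j;
* the *functional parametrisation* x = A(omega-jet, zeta-jet),
  u = B(omega-jet, zeta-jet) that replaces the differential equations;
* the linearising feedback u = A^{-1}(v - b) rendering omega_i^(kappa_i) = v_i;
* the Brunovsky chain realisation and polynomial point-to-point plans.

Scope: static-feedback-linearisable systems.  A candidate whose input
direction appears but is dependent on previously gathered ones would require
genuine dynamic extension and is rejected with a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from sympy.core.function import AppliedUndef

from .model import ControlAffineModel, jet_symbol, jet_order
from .reference import ReferenceTrajectory

__all__ = [
    "FlatnessError",
    "CandidateRejected",
    "SingularDecouplingMatrix",
    "ParametrisationError",
    "FlatnessCertificate",
    "FunctionalParametrisation",
    "ChainRealisation",
    "brunovsky_analysis",
    "functional_parametrisation",
    "verify_parametrisation",
    "linearising_feedback",
    "LinearisingFeedback",
    "brunovsky_realisation",
    "plan_point_to_point",
    "generically_zero",
]


class FlatnessError(RuntimeError):
    pass


class CandidateRejected(FlatnessError):
    pass


class SingularDecouplingMatrix(FlatnessError):
    pass


class ParametrisationError(FlatnessError):
    pass


# ---------------------------------------------------------------------------
# generic zero / rank testing
# ---------------------------------------------------------------------------

_ZERO_SEED = 20240901


def _mask_undefined(expr: sp.Expr) -> sp.Expr:
    """Replace undefined function applications (and their derivatives) by
    fresh symbols, consistently by structure, so numeric probing can proceed."""
    expr = sp.sympify(expr)
    atoms = sorted(expr.atoms(sp.Derivative), key=sp.srepr) + sorted(
        (a for a in expr.atoms(AppliedUndef)), key=sp.srepr
    )
    for i, a in enumerate(atoms):
        expr = expr.subs(a, sp.Symbol(f"_undef{i}"))
    return expr


def _probe_points(symbols, npoints: int, seed: int = _ZERO_SEED):
    rng = np.random.default_rng(seed)
    # avoid structured points (0, 1) where expressions may vanish accidentally
    return rng.uniform(0.37, 1.83, size=(npoints, len(symbols)))


def generically_zero(expr, npoints: int = 10, tol: float = 1e-12) -> bool:
    """Zero test: symbolic simplification first, then evaluation at random
    points with relative tolerance ``tol`` as fallback; both must agree for a
    'generically zero' verdict (a symbolic zero is accepted outright)."""
    e = sp.simplify(sp.sympify(expr))
    if e == 0:
        return True
    e = _mask_undefined(e)
    if e == 0:
        return False  # masking cannot create zero; keep conservative
    syms = sorted(e.free_symbols, key=lambda s: s.name)
    f = sp.lambdify(syms, e, "numpy")
    pts = _probe_points(syms, npoints)
    vals = np.array([f(*p) for p in pts], dtype=complex)
    scale = 1.0 + np.max(np.abs(vals))
    return bool(np.max(np.abs(vals)) / scale < tol)


def _generic_rank(matrix: sp.Matrix, npoints: int = 4) -> int:
    """Generic numeric rank of a symbolic matrix (max over random points)."""
    M = sp.Matrix([[_mask_undefined(e) for e in matrix.row(i)] for i in range(matrix.rows)])
    syms = sorted(M.free_symbols, key=lambda s: s.name)
    f = sp.lambdify(syms, M, "numpy")
    best = 0
    for p in _probe_points(syms, npoints):
        A = np.asarray(f(*p), dtype=float)
        best = max(best, int(np.linalg.matrix_rank(A, tol=1e-9)))
    return best


# ---------------------------------------------------------------------------
# certificates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlatnessCertificate:
    """Outcome of the dynamical extension algorithm on a candidate tuple.

    ``chains[i][k]`` is omega_i^(k) expressed in state and fluctuation jets
    for k < kappa_i; ``decoupling`` and ``drift`` give
    omega_i^(kappa_i) = drift[i] + sum_j decoupling[i, j] * u_j.
    """

    model: ControlAffineModel
    candidates: tuple
    kappas: tuple
    chains: tuple
    decoupling: sp.Matrix
    drift: tuple
    flat: bool
    diagnostics: str = ""

    @property
    def total_index(self) -> int:
        return sum(self.kappas)

    @property
    def omega_bases(self) -> tuple:
        return tuple(f"omega{i + 1}" for i in range(len(self.candidates)))

    def omega_jet(self, i: int, k: int) -> sp.Symbol:
        return jet_symbol(self.omega_bases[i], k)


def brunovsky_analysis(model: ControlAffineModel, candidates) -> FlatnessCertificate:
    """Dynamical extension algorithm, Phases I and II.

    Each candidate (a function of states and fluctuations, never of inputs)
    is differentiated along the model flow until a combination of control
    inputs appears that is generically independent of those gathered for the
    previous components; the number of differentiations is the Brunovsky
    index kappa_i.  The tuple is certified flat iff sum(kappa) equals the
    state dimension and the decoupling matrix is generically invertible.
    """
    candidates = tuple(sp.sympify(c) for c in candidates)
    if len(candidates) != model.m:
        raise CandidateRejected(
            f"need one candidate per input ({model.m}), got {len(candidates)}"
        )
    for c in candidates:
        if set(c.free_symbols) & set(model.inputs):
            raise CandidateRejected(
                f"candidate {c} depends on an input symbol; flat-output "
                "candidates must be endogenous functions of state and fluctuations"
            )
    cap = 2 * model.n
    kappas, chains, rows, drifts = [], [], [], []
    for i, cand in enumerate(candidates):
        expr = sp.sympify(cand)
        chain_i = []
        k = 0
        while True:
            expr = sp.expand(expr)
            row = [sp.expand(expr.coeff(u, 1)) for u in model.inputs]
            rest = sp.expand(expr - sum(r * u for r, u in zip(row, model.inputs)))
            if set(rest.free_symbols) & set(model.inputs):
                raise CandidateRejected(
                    f"candidate {cand}: derivative {k} is not affine in the "
                    "inputs; model is not control-affine along this chain"
                )
            if any(r != 0 for r in row):
                independent = True
                if rows:
                    independent = _generic_rank(sp.Matrix(rows + [row])) > _generic_rank(sp.Matrix(rows))
                if independent:
                    kappas.append(k)
                    rows.append(row)
                    drifts.append(rest)
                    chains.append(tuple(chain_i))
                    break
                raise CandidateRejected(
                    f"candidate {cand}: input direction at order {k} is "
                    "dependent on previously gathered directions; dynamic "
                    "extension would be required (out of scope)"
                )
            chain_i.append(expr)
            if k >= cap:
                raise CandidateRejected(
                    f"candidate {cand}: no input appeared within {cap} "
                    "differentiations"
                )
            expr = model.total_derivative(expr)
            k += 1
    A = sp.Matrix(rows)
    flat = sum(kappas) == model.n and _generic_rank(A) == model.m
    diag = ""
    if sum(kappas) != model.n:
        diag = (f"sum of Brunovsky indices {sum(kappas)} != state dimension "
                f"{model.n}; candidate tuple is not a flat output")
    elif _generic_rank(A) != model.m:
        diag = "decoupling matrix is generically singular"
    return FlatnessCertificate(
        model=model,
        candidates=candidates,
        kappas=tuple(kappas),
        chains=tuple(chains),
        decoupling=A,
        drift=tuple(drifts),
        flat=flat,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# functional parametrisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionalParametrisation:
    """x = A(omega-jet, zeta-jet), u = B(omega-jet, zeta-jet)."""

    certificate: FlatnessCertificate
    x_exprs: tuple
    u_exprs: tuple
    alpha_x: int
    alpha_u: int

    @property
    def model(self) -> ControlAffineModel:
        return self.certificate.model

    def omega_jet_symbols(self, max_order: int | None = None):
        cert = self.certificate
        out = []
        for i, kap in enumerate(cert.kappas):
            top = kap if max_order is None else max_order
            out.extend(cert.omega_jet(i, k) for k in range(top + 1))
        return out


def functional_parametrisation(
    model: ControlAffineModel, cert: FlatnessCertificate
) -> FunctionalParametrisation:
    """Invert the stacked derivative chains for the state, then the decoupling
    relation for the input."""
    if not cert.flat:
        raise ParametrisationError(
            f"certificate is not flat: {cert.diagnostics or 'sum kappa < n'}"
        )
    eqs = []
    for i, kap in enumerate(cert.kappas):
        for k in range(kap):
            eqs.append(sp.Eq(cert.chains[i][k], cert.omega_jet(i, k)))
    sols = sp.solve(eqs, list(model.states), dict=True)
    if not sols:
        raise ParametrisationError(
            "symbolic solve of the derivative-chain map for the state failed; "
            f"equations: {eqs}"
        )
    sol = sols[0]
    if len(sol) != model.n:
        raise ParametrisationError(f"chain map only solvable for {list(sol)}")
    x_exprs = tuple(sp.simplify(sol[x]) for x in model.states)
    top = sp.Matrix([cert.omega_jet(i, kap) for i, kap in enumerate(cert.kappas)])
    A = cert.decoupling.subs(sol)
    b = sp.Matrix(cert.drift).subs(sol)
    u_vec = A.solve(top - b)
    u_exprs = tuple(sp.simplify(u) for u in u_vec)
    return FunctionalParametrisation(
        certificate=cert,
        x_exprs=x_exprs,
        u_exprs=u_exprs,
        alpha_x=max(cert.kappas) - 1,
        alpha_u=max(cert.kappas),
    )


def _jet_shift(model: ControlAffineModel, cert: FlatnessCertificate, expr: sp.Expr) -> sp.Expr:
    """Time derivative of an expression in omega-jets and zeta-jets, using the
    trivial shift rules d/dt omega_i^(k) = omega_i^(k+1), likewise for zeta."""
    expr = sp.sympify(expr)
    out = sp.S.Zero
    bases = set(cert.omega_bases) | set(model.fluctuations)
    for s in expr.free_symbols:
        base, order = jet_order(s)
        if base in bases:
            out += sp.diff(expr, s) * jet_symbol(base, order + 1)
    return out


def verify_parametrisation(
    model: ControlAffineModel, par: FunctionalParametrisation
):
    """Substitute the parametrisation into the model equations.

    Returns the simplified residual of each state equation (all zero for a
    valid parametrisation); nonzero residuals are the informative return, not
    an error.
    """
    cert = par.certificate
    subs = {x: e for x, e in zip(model.states, par.x_exprs)}
    subs.update({u: e for u, e in zip(model.inputs, par.u_exprs)})
    rhs = [e.subs(subs) for e in model.rhs(with_params=False)]
    residuals = []
    for i, x in enumerate(model.states):
        lhs = _jet_shift(model, cert, par.x_exprs[i])
        residuals.append(sp.simplify(lhs - rhs[i]))
    return tuple(residuals)


# ---------------------------------------------------------------------------
# linearising feedback
# ---------------------------------------------------------------------------

def _jet_specs_in(model: ControlAffineModel, exprs) -> list:
    specs = set()
    for e in exprs:
        for s in sp.sympify(e).free_symbols:
            base, order = jet_order(s)
            if base in model.fluctuations:
                specs.add((base, order))
    return sorted(specs, key=lambda bk: (model.fluctuations.index(bk[0]), bk[1]))


class LinearisingFeedback:
    """u = A(x, zeta)^{-1} (v - b(x, zeta)); closes omega_i^(kappa_i) = v_i."""

    def __init__(self, model: ControlAffineModel, cert: FlatnessCertificate,
                 det_tol: float = 1e-12):
        self.model = model
        self.cert = cert
        self.det_tol = det_tol
        v = sp.Matrix([sp.Symbol(f"v{i + 1}") for i in range(model.m)])
        A = cert.decoupling
        b = sp.Matrix(cert.drift)
        self.u_exprs = tuple(A.solve(v - b))
        self.jet_specs = _jet_specs_in(model, list(A) + list(b))
        jet_syms = [jet_symbol(b_, k) for b_, k in self.jet_specs]
        args = list(model.states) + list(v) + jet_syms
        self._u_fn = sp.lambdify(
            args, [model.subs_params(e) for e in self.u_exprs], "numpy"
        )
        self._det_fn = sp.lambdify(
            list(model.states) + jet_syms, model.subs_params(A.det()), "numpy"
        )

    def __call__(self, x, v, jets=None) -> np.ndarray:
        jv = [jets[spec] for spec in self.jet_specs] if self.jet_specs else []
        det = float(self._det_fn(*x, *jv))
        if abs(det) < self.det_tol:
            raise SingularDecouplingMatrix(
                f"decoupling matrix singular (det={det:.3e}) at x={np.asarray(x)}"
            )
        return np.asarray(self._u_fn(*x, *v, *jv), dtype=float).reshape(-1)


def linearising_feedback(model: ControlAffineModel, cert: FlatnessCertificate) -> LinearisingFeedback:
    if not cert.flat:
        raise FlatnessError("linearising feedback requires a flat certificate")
    return LinearisingFeedback(model, cert)


# ---------------------------------------------------------------------------
# Brunovsky chain realisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainRealisation:
    """State-space realisation on the flat-output jets.

    State z stacks (omega_1, ..., omega_1^(kappa_1-1), omega_2, ...); all but
    the top of each block are pure integrations, and each block is closed by
    gamma_i = b_i + sum_j A_ij u_j with the state rewritten through the
    functional parametrisation.
    """

    certificate: FlatnessCertificate
    parametrisation: FunctionalParametrisation
    z_symbols: tuple
    rhs_exprs: tuple  # in z, u, zeta-jets
    block_slices: tuple

    @property
    def dim(self) -> int:
        return len(self.z_symbols)


def brunovsky_realisation(
    cert: FlatnessCertificate, par: FunctionalParametrisation | None = None
) -> ChainRealisation:
    if not cert.flat:
        raise FlatnessError("realisation requires a flat certificate")
    model = cert.model
    if par is None:
        par = functional_parametrisation(model, cert)
    z_syms, slices, pos = [], [], 0
    for i, kap in enumerate(cert.kappas):
        z_syms.extend(cert.omega_jet(i, k) for k in range(kap))
        slices.append((pos, pos + kap))
        pos += kap
    x_subs = {x: e for x, e in zip(model.states, par.x_exprs)}
    rhs = []
    for i, kap in enumerate(cert.kappas):
        for k in range(kap - 1):
            rhs.append(cert.omega_jet(i, k + 1))
        gamma = cert.drift[i] + sum(
            cert.decoupling[i, j] * model.inputs[j] for j in range(model.m)
        )
        rhs.append(sp.simplify(gamma.subs(x_subs)))
    return ChainRealisation(
        certificate=cert,
        parametrisation=par,
        z_symbols=tuple(z_syms),
        rhs_exprs=tuple(rhs),
        block_slices=tuple(slices),
    )


# ---------------------------------------------------------------------------
# point-to-point planning
# ---------------------------------------------------------------------------

def _chain_values(cert: FlatnessCertificate, x: np.ndarray) -> list:
    """Mean-model omega-jets (orders < kappa_i) at a state point."""
    model = cert.model
    out = []
    for i, kap in enumerate(cert.kappas):
        vals = []
        for k in range(kap):
            e = model.subs_params(cert.chains[i][k])
            e = e.subs({jet_symbol(b_, o): 0 for b_, o in _jet_specs_in(model, [e])})
            fn = sp.lambdify(list(model.states), e, "numpy")
            vals.append(float(fn(*x)))
        out.append(vals)
    return out


def plan_point_to_point(
    model: ControlAffineModel,
    cert: FlatnessCertificate,
    x0,
    x1,
    t0: float,
    t1: float,
) -> ReferenceTrajectory:
    """Polynomial flat-output reference steering the mean model x0 -> x1.

    Per component the unique polynomial of degree 2*kappa_i - 1 matching the
    kappa_i endpoint jet conditions (Hermite interpolation); the open-loop
    input from the functional parametrisation then realises the transfer
    exactly on the noise-free model.
    """
    if not cert.flat:
        raise FlatnessError("planning requires a flat certificate")
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    jets0 = _chain_values(cert, x0)
    jets1 = _chain_values(cert, x1)
    T = t1 - t0
    t = sp.Symbol("t")
    exprs = []
    for i, kap in enumerate(cert.kappas):
        deg = 2 * kap - 1
        ncoef = deg + 1
        M = np.zeros((ncoef, ncoef))
        rhs = np.zeros(ncoef)
        # scaled variable s = (t - t0)/T for conditioning
        for k in range(kap):
            for e in range(k, ncoef):
                fall = np.prod(np.arange(e, e - k, -1)) if k else 1.0
                M[k, e] = fall * (0.0 ** (e - k) if e > k else 1.0)
                M[kap + k, e] = fall  # s = 1
            rhs[k] = jets0[i][k] * T**k
            rhs[kap + k] = jets1[i][k] * T**k
        coef = np.linalg.solve(M, rhs)
        s = (t - t0) / T
        exprs.append(sp.expand(sum(c * s**e for e, c in enumerate(coef))))
    return ReferenceTrajectory(
        exprs, t, max_order=max(cert.kappas), domain=(t0, t1),
        name="point_to_point",
    )
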