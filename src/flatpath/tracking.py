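"""Flatness-based trajectory tracking and pathwise closed-loop simulation.

The tracking law operates on the exactly linearised flat-output dynamics
omega_i^(kappa_i) = v_i:

    v_i = omega_ref_i^(kappa_i) - sum_{j<kappa_i} lambda_{i,j} (omega_i^(j) - omega_ref_i^(j))

so the action discrepancy eps_act = omega - omega_ref obeys the Hurwitz error
dynamics e^(kappa) + sum_j lambda_j e^(j) = 0.  Controllers come in two modes:

``oracle``
    the paper's full-knowledge assumption — true fluctuation jets are
    substituted into chains and feedback;
``mean``
    all fluctuation-jet terms are set to zero (the agent only knows the mean
    generative model).

Closed loops are random ODEs integrated pathwise with a fixed-step classical
4th-order Runge-Kutta scheme; given the same seed and step the trace is
bit-reproducible.  Discrepancy metrics report the observation and action
discrepancies and a Gaussian risk proxy int 1/2 eps_act^T Pi eps_act dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp

from .flat_core import (
    FlatnessCertificate,
    FunctionalParametrisation,
    LinearisingFeedback,
    _jet_specs_in,
    linearising_feedback,
)
from .model import ControlAffineModel, NoiseBinding, jet_symbol
from .reference import ReferenceTrajectory

__all__ = [
    "TrackingGains",
    "hurwitz_gains",
    "tracking_v",
    "TrackingController",
    "OpenLoopController",
    "ZeroController",
    "tracking_controller",
    "open_loop_controller",
    "simulate_closed_loop",
    "simulate_chain",
    "SimulationTrace",
    "RiskConfig",
    "DiscrepancyMetrics",
    "discrepancy_metrics",
    "fit_decay_rate",
]


# ---------------------------------------------------------------------------
# gains
# ---------------------------------------------------------------------------

def hurwitz_gains(kappa: int, pole: float) -> tuple:
    """Coefficients (lambda_0, ..., lambda_{kappa-1}) of (s + pole)^kappa with
    the leading coefficient dropped: a kappa-fold pole at -pole."""
    if pole <= 0:
        raise ValueError(f"designed pole must be positive, got {pole}")
    from math import comb

    return tuple(comb(kappa, j) * pole ** (kappa - j) for j in range(kappa))


@dataclass(frozen=True)
class TrackingGains:
    """Per-component error-feedback coefficients lambda_{i,0..kappa_i-1}."""

    coefficients: tuple
    pole: float | None = None

    def __post_init__(self) -> None:
        coeffs = tuple(tuple(float(c) for c in row) for row in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        for row in coeffs:
            poly = np.concatenate(([1.0], np.array(row)[::-1]))
            roots = np.roots(poly)
            if np.any(roots.real >= -1e-12):
                raise ValueError(
                    f"gain row {row} is not Hurwitz (roots {roots})"
                )

    @classmethod
    def pole_placement(cls, kappas, pole: float) -> "TrackingGains":
        return cls(tuple(hurwitz_gains(k, pole) for k in kappas), pole=pole)


def tracking_v(measured_jets, reference_jets, gains: TrackingGains) -> np.ndarray:
    """New input v_i = ref_i^(kappa_i) - sum_j lambda_ij (omega_i^(j) - ref_i^(j)).

    ``measured_jets[i]`` holds orders 0..kappa_i-1 of component i;
    ``reference_jets[i]`` holds orders 0..kappa_i.
    """
    v = []
    for meas, ref, lam in zip(measured_jets, reference_jets, gains.coefficients):
        kappa = len(lam)
        if len(meas) < kappa or len(ref) < kappa + 1:
            raise ValueError("jet order mismatch with gain length")
        err = np.asarray(meas[:kappa], dtype=float) - np.asarray(ref[:kappa], dtype=float)
        v.append(float(ref[kappa]) - float(np.dot(lam, err)))
    return np.array(v)


# ---------------------------------------------------------------------------
# controllers
# ---------------------------------------------------------------------------

class TrackingController:
    """Tracking law composed of the chain evaluators, the v-law and the
    linearising feedback u = A^{-1}(v - b)."""

    def __init__(self, model: ControlAffineModel, cert: FlatnessCertificate,
                 reference: ReferenceTrajectory, gains: TrackingGains,
                 mode: str = "oracle"):
        if not cert.flat:
            raise ValueError("tracking controller requires a flat certificate")
        if mode not in ("oracle", "mean"):
            raise ValueError(f"unknown controller mode {mode!r}")
        if reference.max_order < max(cert.kappas):
            raise ValueError(
                f"reference must be differentiable to order {max(cert.kappas)}"
            )
        self.model, self.cert = model, cert
        self.reference, self.gains, self.mode = reference, gains, mode
        chain_exprs = [list(ch) for ch in cert.chains]
        if mode == "mean":
            flat_list = [e for ch in chain_exprs for e in ch]
            zsubs = {jet_symbol(b, k): 0 for b, k in _jet_specs_in(model, flat_list)}
            chain_exprs = [[e.subs(zsubs) for e in ch] for ch in chain_exprs]
            mean_cert = FlatnessCertificate(
                model=model, candidates=cert.candidates, kappas=cert.kappas,
                chains=tuple(tuple(ch) for ch in chain_exprs),
                decoupling=cert.decoupling.subs(
                    {jet_symbol(b, k): 0
                     for b, k in _jet_specs_in(model, list(cert.decoupling))}),
                drift=tuple(e.subs({jet_symbol(b, k): 0
                                    for b, k in _jet_specs_in(model, list(cert.drift))})
                            for e in cert.drift),
                flat=True)
            self.feedback = LinearisingFeedback(model, mean_cert)
        else:
            self.feedback = linearising_feedback(model, cert)
        flat_list = [e for ch in chain_exprs for e in ch]
        self.chain_jet_specs = _jet_specs_in(model, flat_list)
        jet_syms = [jet_symbol(b, k) for b, k in self.chain_jet_specs]
        self._chain_fns = [
            sp.lambdify(list(model.states) + jet_syms,
                        [model.subs_params(e) for e in ch], "numpy")
            for ch in chain_exprs
        ]
        self.jet_specs = sorted(
            set(self.chain_jet_specs) | set(self.feedback.jet_specs),
            key=lambda bk: (model.fluctuations.index(bk[0]), bk[1]),
        )

    def measured_jets(self, x, jets=None):
        jv = ([jets[s] for s in self.chain_jet_specs]
              if self.chain_jet_specs else [])
        return [np.atleast_1d(np.asarray(fn(*x, *jv), dtype=float))
                for fn in self._chain_fns]

    def __call__(self, t: float, x, jets=None) -> np.ndarray:
        meas = self.measured_jets(x, jets)
        ref = self.reference.jets(t, max(self.cert.kappas))
        v = tracking_v(meas, ref, self.gains)
        return self.feedback(x, v, jets)


class OpenLoopController:
    """u(t) = B(omega_ref-jet(t), zeta-jet(t)) from the functional
    parametrisation; no state feedback."""

    def __init__(self, par: FunctionalParametrisation,
                 reference: ReferenceTrajectory, mode: str = "mean"):
        cert = par.certificate
        model = cert.model
        self.par, self.reference, self.mode = par, reference, mode
        u_exprs = list(par.u_exprs)
        if mode == "mean":
            zsubs = {jet_symbol(b, k): 0 for b, k in _jet_specs_in(model, u_exprs)}
            u_exprs = [e.subs(zsubs) for e in u_exprs]
        self.jet_specs = _jet_specs_in(model, u_exprs)
        self._w_syms = []
        for i, kap in enumerate(cert.kappas):
            self._w_syms.append([cert.omega_jet(i, k) for k in range(kap + 1)])
        w_flat = [s for row in self._w_syms for s in row]
        jet_syms = [jet_symbol(b, k) for b, k in self.jet_specs]
        self._u_fn = sp.lambdify(
            w_flat + jet_syms, [model.subs_params(e) for e in u_exprs], "numpy"
        )
        self._kappas = cert.kappas

    def __call__(self, t: float, x=None, jets=None) -> np.ndarray:
        ref = self.reference.jets(t, max(self._kappas))
        w_vals = []
        for i, kap in enumerate(self._kappas):
            w_vals.extend(ref[i][: kap + 1])
        jv = [jets[s] for s in self.jet_specs] if self.jet_specs else []
        return np.asarray(self._u_fn(*w_vals, *jv), dtype=float).reshape(-1)


class ZeroController:
    jet_specs: list = []

    def __init__(self, m: int = 1):
        self.m = m

    def __call__(self, t, x=None, jets=None) -> np.ndarray:
        return np.zeros(self.m)


def tracking_controller(model, cert, reference, gains, mode="oracle") -> TrackingController:
    return TrackingController(model, cert, reference, gains, mode)


def open_loop_controller(par, reference, mode="mean") -> OpenLoopController:
    return OpenLoopController(par, reference, mode)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Time-indexed paths of a closed-loop run."""

    t: np.ndarray
    x: np.ndarray          # (nt, n)
    u: np.ndarray          # (nt, m)
    omega: np.ndarray | None = None      # flat output path (nt, m)
    reference: np.ndarray | None = None  # omega_ref path (nt, m)
    eps_act: np.ndarray | None = None    # omega - omega_ref
    y: np.ndarray | None = None          # sensed output (with fluctuations)
    y_hat: np.ndarray | None = None      # predicted output (mean observation)
    eps_obs: np.ndarray | None = None    # y - y_hat
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.x.shape[0] != self.t.size or self.u.shape[0] != self.t.size:
            raise ValueError("inconsistent trace shapes")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for i in range(self.x.shape[1]):
            cols[f"x{i + 1}"] = self.x[:, i]
        for j in range(self.u.shape[1]):
            cols[f"u{j + 1}"] = self.u[:, j]
        for name, arr in (("omega", self.omega), ("ref", self.reference),
                          ("eps_act", self.eps_act), ("y", self.y),
                          ("eps_obs", self.eps_obs)):
            if arr is not None:
                for i in range(arr.shape[1]):
                    cols[f"{name}{i + 1}"] = arr[:, i]
        return pd.DataFrame(cols)


def _rk4(deriv, x0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    x = np.empty((t_grid.size, x0.size))
    x[0] = x0
    for i in range(t_grid.size - 1):
        t, h = t_grid[i], t_grid[i + 1] - t_grid[i]
        xi = x[i]
        k1 = deriv(t, xi)
        k2 = deriv(t + h / 2, xi + h / 2 * k1)
        k3 = deriv(t + h / 2, xi + h / 2 * k2)
        k4 = deriv(t + h, xi + h * k3)
        x[i + 1] = xi + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x[i + 1])):
            raise RuntimeError(f"state became non-finite at t={t_grid[i + 1]:.6g}")
    return x


def simulate_closed_loop(
    model: ControlAffineModel,
    controller,
    binding: NoiseBinding | None,
    x0,
    t_span,
    dt: float,
    reference: ReferenceTrajectory | None = None,
    cert: FlatnessCertificate | None = None,
    metadata: dict | None = None,
) -> SimulationTrace:
    """Fixed-step RK4 integration of the pathwise closed loop.

    ``controller(t, x, jets) -> u``; fluctuations are bound per base name and
    their formal derivatives evaluated exactly at every integrator stage.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t1 = float(t_span[0]), float(t_span[1])
    nsteps = int(round((t1 - t0) / dt))
    t_grid = t0 + dt * np.arange(nsteps + 1)
    rhs_exprs = list(model.rhs(with_params=True))
    rhs_specs = _jet_specs_in(model, rhs_exprs)
    ctrl_specs = list(getattr(controller, "jet_specs", []))
    all_specs = sorted(set(rhs_specs) | set(ctrl_specs),
                       key=lambda bk: (model.fluctuations.index(bk[0]), bk[1]))
    if all_specs and binding is None:
        raise ValueError("model/controller use fluctuations but no binding given")
    binding = binding or NoiseBinding.zero(model.fluctuations)
    jet_syms = [jet_symbol(b, k) for b, k in all_specs]
    rhs_fn = sp.lambdify(
        list(model.states) + list(model.inputs) + jet_syms, rhs_exprs, "numpy"
    )

    def jets_at(t: float) -> dict:
        return binding.jets(t, all_specs)

    def deriv(t, x):
        jets = jets_at(t)
        u = controller(t, x, jets)
        jv = [jets[s] for s in all_specs]
        return np.asarray(rhs_fn(*x, *u, *jv), dtype=float)

    x_path = _rk4(deriv, np.asarray(x0, dtype=float), t_grid)
    u_path = np.array([controller(t, x, jets_at(t)) for t, x in zip(t_grid, x_path)])

    omega = ref = eps_act = None
    used_cert = cert or getattr(controller, "cert", None)
    used_ref = reference or getattr(controller, "reference", None)
    if used_cert is not None:
        cand = [model.subs_params(c) for c in used_cert.candidates]
        cand_specs = _jet_specs_in(model, cand)
        cand_fn = sp.lambdify(
            list(model.states) + [jet_symbol(b, k) for b, k in cand_specs],
            cand, "numpy")
        omega = np.array([
            np.atleast_1d(cand_fn(*x, *[binding.jets(t, cand_specs)[s]
                                        for s in cand_specs]))
            for t, x in zip(t_grid, x_path)
        ], dtype=float)
    if used_ref is not None and omega is not None:
        ref = np.array([used_ref.value(t) for t in t_grid], dtype=float)
        eps_act = omega - ref

    y = y_hat = eps_obs = None
    if model.outputs:
        out_exprs = [model.subs_params(h) for h in model.outputs]
        out_specs = _jet_specs_in(model, out_exprs)
        out_syms = [jet_symbol(b, k) for b, k in out_specs]
        y_fn = sp.lambdify(list(model.states) + out_syms, out_exprs, "numpy")
        yhat_fn = sp.lambdify(
            list(model.states),
            [e.subs({s: 0 for s in out_syms}) for e in out_exprs], "numpy")
        y = np.array([np.atleast_1d(y_fn(*x, *[binding.jets(t, out_specs)[s]
                                               for s in out_specs]))
                      for t, x in zip(t_grid, x_path)], dtype=float)
        y_hat = np.array([np.atleast_1d(yhat_fn(*x)) for x in x_path], dtype=float)
        eps_obs = y - y_hat

    meta = {"dt": dt, "mode": getattr(controller, "mode", type(controller).__name__)}
    gains = getattr(controller, "gains", None)
    if gains is not None:
        meta["gains"] = gains.coefficients
        meta["pole"] = gains.pole
    meta.update(metadata or {})
    return SimulationTrace(
        t=t_grid, x=x_path, u=u_path, omega=omega, reference=ref,
        eps_act=eps_act, y=y, y_hat=y_hat, eps_obs=eps_obs, metadata=meta,
    )


def simulate_chain(realisation, controller_or_upath, binding, z0, t_span, dt):
    """Integrate a Brunovsky chain realisation under a given input path.

    ``controller_or_upath`` is either a controller (t, z, jets) -> u or a
    plain callable t -> u.  Returns (t_grid, z_path).
    """
    model = realisation.certificate.model
    t0, t1 = float(t_span[0]), float(t_span[1])
    nsteps = int(round((t1 - t0) / dt))
    t_grid = t0 + dt * np.arange(nsteps + 1)
    exprs = [model.subs_params(e) for e in realisation.rhs_exprs]
    specs = _jet_specs_in(model, exprs)
    binding = binding or NoiseBinding.zero(model.fluctuations)
    jet_syms = [jet_symbol(b, k) for b, k in specs]
    fn = sp.lambdify(
        list(realisation.z_symbols) + list(model.inputs) + jet_syms, exprs, "numpy"
    )

    def deriv(t, z):
        jets = binding.jets(t, specs)
        try:
            u = np.atleast_1d(controller_or_upath(t, z, jets))
        except TypeError:
            u = np.atleast_1d(controller_or_upath(t))
        return np.asarray(fn(*z, *u, *[jets[s] for s in specs]), dtype=float)

    z_path = _rk4(deriv, np.asarray(z0, dtype=float), t_grid)
    return t_grid, z_path


# ---------------------------------------------------------------------------
# discrepancies and risk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskConfig:
    """Precision weights for the Gaussian risk proxy."""

    precision: np.ndarray
    rule: str = "trapezoid"

    def __post_init__(self) -> None:
        P = np.atleast_2d(np.asarray(self.precision, dtype=float))
        if not np.allclose(P, P.T):
            raise ValueError("precision must be symmetric")
        if np.any(np.linalg.eigvalsh(P) <= 0):
            raise ValueError("precision must be positive definite")
        object.__setattr__(self, "precision", P)
        if self.rule != "trapezoid":
            raise ValueError(f"unsupported integration rule {self.rule!r}")


@dataclass(frozen=True)
class DiscrepancyMetrics:
    eps_act: np.ndarray
    eps_obs: np.ndarray | None
    integrated_squared_error: float
    risk: float


def fit_decay_rate(trace: SimulationTrace, window=(0.2, 0.8),
                   floor: float = 1e-12) -> float:
    """Exponential decay rate of ||eps_act|| by a log-linear fit.

    The fit uses the [window[0], window[1]] fraction of the run, truncated at
    the numerical noise floor; returns the positive decay rate p such that
    ||eps_act|| ~ exp(-p t).
    """
    if trace.eps_act is None:
        raise ValueError("trace has no action discrepancy")
    norm = np.linalg.norm(trace.eps_act, axis=1)
    T = trace.t[-1] - trace.t[0]
    lo, hi = trace.t[0] + window[0] * T, trace.t[0] + window[1] * T
    sel = (trace.t >= lo) & (trace.t <= hi) & (norm > floor)
    if sel.sum() < 10:
        raise ValueError("not enough points above the noise floor to fit")
    slope = np.polyfit(trace.t[sel], np.log(norm[sel]), 1)[0]
    return float(-slope)


def discrepancy_metrics(trace: SimulationTrace, risk: RiskConfig) -> DiscrepancyMetrics:
    """Action/observation discrepancies and the pathwise Gaussian risk proxy
    int 1/2 eps_act(t)^T Pi eps_act(t) dt (trapezoid rule), the
    equal-covariance Kullback-Leibler divergence between anticipated and
    goal-conditioned outcome densities integrated along the path."""
    if trace.eps_act is None:
        raise ValueError("trace has no action discrepancy (no reference given)")
    e = trace.eps_act
    ise = float(np.trapezoid((e**2).sum(axis=1), trace.t))
    quad = 0.5 * np.einsum("ti,ij,tj->t", e, risk.precision, e)
    return DiscrepancyMetrics(
        eps_act=e,
        eps_obs=trace.eps_obs,
        integrated_squared_error=ise,
        risk=float(np.trapezoid(quad, trace.t)),
    )
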