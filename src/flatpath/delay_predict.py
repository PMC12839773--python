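"""Input delays: delta-flatness, state predictors, predictive tracking.

A model with input delay tau,

    x'(t) = f(x(t)) + G(x(t)) u(t - tau),

remains flat if one allows the time-shift operator in the parametrisation
(delta-flatness): the action is expressed through the flat output evaluated
at t + tau.  Tracking then requires predicting the state one delay ahead.
Two predictors are provided:

* a **delayed observer** x_hat'(t) = f(x_hat(t), u(t)) + K (x(t) - x_hat(t - tau)),
  whose prediction error x(t) - x_hat(t - tau) decays for stabilising K;
* an **integral predictor** solving the implicit relation
  p(t) = x(t) + int_{t-tau}^{t} f(p(xi), u(xi)) dxi
  by damped-free Picard iteration with trapezoidal quadrature (p(t)
  approximates x(t + tau), since the input acting on the plant during
  [t, t + tau] is the already-commanded history on [t - tau, t]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .flat_core import _jet_specs_in
from .model import ControlAffineModel, NoiseBinding, jet_symbol
from .tracking import SimulationTrace

__all__ = [
    "DelayedModel",
    "PredictorConfig",
    "PredictorDiverged",
    "UniformHistory",
    "delta_flat_parametrisation",
    "DeltaFlatParametrisation",
    "delayed_observer_simulate",
    "integral_predictor",
    "simulate_predictive_tracking",
]


class PredictorDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class DelayedModel:
    """A control-affine model whose input acts with delay tau >= 0."""

    base: ControlAffineModel
    tau: float

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("delay must be >= 0")


@dataclass(frozen=True)
class PredictorConfig:
    kind: str = "integral"  # or "delayed_observer"
    K_obs: np.ndarray | None = None
    quad_step: float | None = None  # defaults to tau/200
    tol: float = 1e-10
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("integral", "delayed_observer"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("need tol > 0 and max_iter >= 1")


class UniformHistory:
    """Uniform-step ring-like history with linear interpolation."""

    def __init__(self, t0: float, dt: float, values: np.ndarray):
        self.t0 = float(t0)
        self.dt = float(dt)
        self.values = [np.atleast_1d(np.asarray(v, dtype=float)) for v in values]

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (len(self.values) - 1)

    def append(self, value) -> None:
        self.values.append(np.atleast_1d(np.asarray(value, dtype=float)))

    def __call__(self, t: float) -> np.ndarray:
        s = (t - self.t0) / self.dt
        i = int(np.floor(s))
        if i < 0:
            return self.values[0]
        if i >= len(self.values) - 1:
            return self.values[-1]
        w = s - i
        return (1 - w) * self.values[i] + w * self.values[i + 1]


# ---------------------------------------------------------------------------
# delta-flat parametrisation of the delayed simple example
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaFlatParametrisation:
    """Shifted-time functional parametrisation of the delayed simple example.

    Expressions are sympy time functions of the symbol ``t``; the action
    carries argument t + tau throughout.
    """

    t: sp.Symbol
    tau: sp.Symbol
    x1: sp.Expr
    x2: sp.Expr
    u: sp.Expr
    f: object  # callable (x1, x2) -> expr

    def residuals(self):
        """Substitute the parametrisation into the delayed model equations
        (with shift algebra) and simplify; returns one residual per state."""
        t, tau = self.t, self.tau
        zx1 = sp.Function("zeta_x1")
        zx2 = sp.Function("zeta_x2")
        r1 = sp.simplify(sp.diff(self.x1, t) - self.x2 - zx1(t))
        u_delayed = self.u.subs(t, t - tau)
        r2 = sp.simplify(
            sp.diff(self.x2, t) - self.f(self.x1, self.x2) - u_delayed - zx2(t)
        )
        return (r1, r2)


def delta_flat_parametrisation(f=None) -> DeltaFlatParametrisation:
    """Delta-flat parametrisation of

        x1'(t) = x2(t) + zeta_x1(t)
        x2'(t) = f(x1(t), x2(t)) + u(t - tau) + zeta_x2(t)
        y(t)   = x1(t) + zeta_y(t)

    with y as the delta-flat output:

        x1(t) = y(t) - zeta_y(t)
        x2(t) = y'(t) - zeta_y'(t) - zeta_x1(t)
        u(t)  = y''(t+tau) - f(x1(t+tau), x2(t+tau))
                - zeta_y''(t+tau) - zeta_x1'(t+tau) - zeta_x2(t+tau)

    ``f`` is a callable (x1_expr, x2_expr) -> expr (default: the undefined
    symbolic function f).  With tau = 0 this reduces to the undelayed
    parametrisation.
    """
    t, tau = sp.symbols("t tau")
    y = sp.Function("y")
    zy = sp.Function("zeta_y")
    zx1 = sp.Function("zeta_x1")
    zx2 = sp.Function("zeta_x2")
    if f is None:
        ff = sp.Function("f")
        f = lambda a, b: ff(a, b)  # noqa: E731
    s = t + tau
    x1 = y(t) - zy(t)
    x2 = sp.diff(y(t), t) - sp.diff(zy(t), t) - zx1(t)
    x1_adv = x1.subs(t, s)
    x2_adv = x2.subs(t, s)
    u = (
        sp.diff(y(s), t, 2)
        - f(x1_adv, x2_adv)
        - sp.diff(zy(s), t, 2)
        - sp.diff(zx1(s), t)
        - zx2(s)
    )
    return DeltaFlatParametrisation(t=t, tau=tau, x1=x1, x2=x2, u=u, f=f)


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------

def _mean_rhs_fn(model: ControlAffineModel):
    """Numeric (x, u) -> dx/dt of the mean model."""
    mean = model.mean() if model.fluctuations else model
    exprs = list(mean.rhs(with_params=True))
    fn = sp.lambdify(list(mean.states) + list(mean.inputs), exprs, "numpy")

    def rhs(x, u):
        return np.asarray(fn(*np.atleast_1d(x), *np.atleast_1d(u)), dtype=float)

    return rhs


_GRID_FN_CACHE: dict = {}


def _mean_rhs_grid_fn(model: ControlAffineModel):
    """Vectorised mean rhs: (P (N, n), U (N, m)) -> (N, n).  Cached per model
    instance, since lambdification dominates the per-call cost."""
    cached = _GRID_FN_CACHE.get(id(model))
    if cached is not None:
        return cached
    mean = model.mean() if model.fluctuations else model
    exprs = list(mean.rhs(with_params=True))
    fn = sp.lambdify(list(mean.states) + list(mean.inputs), exprs, "numpy")

    def rhs(P, U):
        out = fn(*(P[:, i] for i in range(P.shape[1])),
                 *(U[:, j] for j in range(U.shape[1])))
        return np.column_stack([np.broadcast_to(o, (P.shape[0],)) for o in out])

    _GRID_FN_CACHE[id(model)] = rhs
    return rhs


def _rhs_fn_with_noise(model: ControlAffineModel, binding: NoiseBinding | None):
    exprs = list(model.rhs(with_params=True))
    specs = _jet_specs_in(model, exprs)
    if specs and binding is None:
        binding = NoiseBinding.zero(model.fluctuations)
    syms = [jet_symbol(b, k) for b, k in specs]
    fn = sp.lambdify(list(model.states) + list(model.inputs) + syms, exprs, "numpy")

    def rhs(t, x, u):
        jv = list(binding.vector(t, specs)) if specs else []
        return np.asarray(fn(*np.atleast_1d(x), *np.atleast_1d(u), *jv), dtype=float)

    return rhs


# ---------------------------------------------------------------------------
# delayed observer
# ---------------------------------------------------------------------------

@dataclass
class DelayedObserverTrace:
    t: np.ndarray
    x: np.ndarray
    x_hat: np.ndarray
    prediction_error: np.ndarray  # x(t) - x_hat(t - tau)
    metadata: dict = field(default_factory=dict)


def delayed_observer_simulate(
    model: DelayedModel,
    K_obs,
    input_path,
    x0,
    xhat_history,
    T: float,
    dt: float = 1e-3,
) -> DelayedObserverTrace:
    """Co-simulate plant and delayed observer under an external input path.

    Plant:     x'(t)     = f(x(t), u(t - tau))
    Observer:  x_hat'(t) = f(x_hat(t), u(t)) + K_obs (x(t) - x_hat(t - tau))

    ``input_path`` must be defined on [-tau, T]; ``xhat_history`` is a
    callable initialising x_hat on [-tau, 0].  The observer state estimates
    x(t + tau); the reported prediction error is x(t) - x_hat(t - tau).
    """
    tau = model.tau
    n = model.base.n
    K = np.atleast_2d(np.asarray(K_obs, dtype=float))
    rhs = _mean_rhs_fn(model.base)
    nsteps = int(round(T / dt))
    t_grid = dt * np.arange(nsteps + 1)
    x = np.empty((nsteps + 1, n))
    xh = np.empty((nsteps + 1, n))
    x[0] = np.atleast_1d(np.asarray(x0, dtype=float))
    xh[0] = np.atleast_1d(np.asarray(xhat_history(0.0), dtype=float))
    nlag = max(1, int(round(tau / dt)))
    hist = UniformHistory(-nlag * dt, dt,
                          [xhat_history(-nlag * dt + i * dt) for i in range(nlag + 1)])

    def deriv(t, state):
        xi, xhi = state[:n], state[n:]
        du = np.atleast_1d(input_path(t - tau))
        u_now = np.atleast_1d(input_path(t))
        innov = xi - hist(t - tau)
        return np.concatenate([rhs(xi, du), rhs(xhi, u_now) + K @ innov])

    state = np.concatenate([x[0], xh[0]])
    for i in range(nsteps):
        t = t_grid[i]
        k1 = deriv(t, state)
        k2 = deriv(t + dt / 2, state + dt / 2 * k1)
        k3 = deriv(t + dt / 2, state + dt / 2 * k2)
        k4 = deriv(t + dt, state + dt * k3)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise RuntimeError(f"state became non-finite at t={t_grid[i + 1]:.6g}")
        x[i + 1], xh[i + 1] = state[:n], state[n:]
        hist.append(xh[i + 1])
    err = np.array([x[i] - hist(t_grid[i] - tau) for i in range(nsteps + 1)])
    return DelayedObserverTrace(
        t=t_grid, x=x, x_hat=xh, prediction_error=err,
        metadata={"tau": tau, "dt": dt, "K_obs": K},
    )


# ---------------------------------------------------------------------------
# integral predictor
# ---------------------------------------------------------------------------

def integral_predictor(
    model: DelayedModel,
    config: PredictorConfig,
    state_history,
    input_history,
    t: float,
    warm_start: np.ndarray | None = None,
):
    """Predicted state ~ x(t + tau) from the implicit integral relation,
    solved by Picard iteration with trapezoidal quadrature.

    ``state_history(s)`` and ``input_history(s)`` must cover [t - tau, t].
    Returns (prediction, info dict).  Raises :class:`PredictorDiverged` if the
    fixed point is not reached within the iteration cap.
    """
    tau = model.tau
    x_t = np.atleast_1d(np.asarray(state_history(t), dtype=float))
    if tau == 0.0:
        return x_t, {"iterations": 0, "residual": 0.0}
    step = config.quad_step or tau / 200.0
    N = max(2, int(round(tau / step)))
    s = np.linspace(t - tau, t, N + 1)
    h = s[1] - s[0]
    rhs = _mean_rhs_grid_fn(model.base)
    u_grid = np.array([np.atleast_1d(input_history(si)) for si in s], dtype=float)
    if warm_start is not None and np.shape(warm_start) == (N + 1, x_t.size):
        p = np.array(warm_start, dtype=float)
    else:
        p = np.tile(x_t, (N + 1, 1))
    for it in range(1, config.max_iter + 1):
        g = rhs(p, u_grid)
        integral = np.concatenate(
            [np.zeros((1, x_t.size)),
             np.cumsum((g[1:] + g[:-1]) / 2 * h, axis=0)]
        )
        p_new = x_t + integral
        res = float(np.max(np.abs(p_new - p)))
        p = p_new
        if res < config.tol:
            return p[-1], {"iterations": it, "residual": res, "window": p}
    raise PredictorDiverged(
        f"Picard iteration did not converge within {config.max_iter} steps "
        f"(last residual {res:.3e})"
    )


# ---------------------------------------------------------------------------
# predictive tracking
# ---------------------------------------------------------------------------

def simulate_predictive_tracking(
    model: DelayedModel,
    controller,
    x0,
    t_span,
    dt: float,
    predictor: PredictorConfig | None = None,
    binding: NoiseBinding | None = None,
    u_prefill=None,
) -> SimulationTrace:
    """Closed-loop tracking of a delayed plant through state prediction.

    At each step the predictor produces x_pred ~ x(t + tau); the (undelayed)
    tracking controller is evaluated at the advanced time on the predicted
    state, u(t) = kappa(t + tau, x_pred), and the plant integrates
    x' = f(x, u(t - tau)) from the commanded-input history.  In oracle mode
    the controller receives the fluctuation jets advanced by tau.
    """
    predictor = predictor or PredictorConfig()
    tau = model.tau
    base = model.base
    t0, t1 = float(t_span[0]), float(t_span[1])
    nsteps = int(round((t1 - t0) / dt))
    t_grid = t0 + dt * np.arange(nsteps + 1)
    nlag = max(1, int(round(tau / dt))) if tau > 0 else 0
    m = base.m
    rhs = _rhs_fn_with_noise(base, binding)
    specs = list(getattr(controller, "jet_specs", []))
    if specs and binding is None:
        binding = NoiseBinding.zero(base.fluctuations)

    def ctrl_jets(t):
        return binding.jets(t, specs) if specs else {}

    if u_prefill is None:
        u_prefill = lambda t: np.zeros(m)  # noqa: E731
    u_hist = UniformHistory(
        t0 - nlag * dt, dt,
        [u_prefill(t0 - nlag * dt + i * dt) for i in range(nlag)] or [np.zeros(m)],
    ) if nlag else None
    x_hist = UniformHistory(t0 - nlag * dt, dt,
                            [np.asarray(x0, float)] * (nlag + 1)) if nlag else None

    obs_state = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    obs_hist = (UniformHistory(t0 - nlag * dt, dt,
                               [obs_state.copy()] * (nlag + 1))
                if (nlag and predictor.kind == "delayed_observer") else None)
    K = (np.atleast_2d(predictor.K_obs)
         if predictor.K_obs is not None else np.eye(base.n))
    mean_rhs = _mean_rhs_fn(base)

    x = np.empty((nsteps + 1, base.n))
    u = np.empty((nsteps + 1, m))
    x[0] = np.asarray(x0, dtype=float)
    warm = None

    def predict(t, xt):
        nonlocal warm, obs_state
        if tau == 0:
            return xt
        if predictor.kind == "integral":
            pred, info = integral_predictor(
                model, predictor, lambda s: x_hist(s) if s < t else xt,
                lambda s: u_hist(s), t, warm_start=warm)
            warm = info.get("window")
            return pred
        return obs_state  # observer estimate of x(t + tau)

    for i in range(nsteps + 1):
        t = t_grid[i]
        xp = predict(t, x[i])
        u[i] = np.atleast_1d(controller(t + tau, xp, ctrl_jets(t + tau)))
        if i == nsteps:
            break
        if nlag:
            u_hist.append(u[i])

            def u_delayed(s):
                return u_hist(s - tau)
        else:
            def u_delayed(s):
                return u[i]

        def deriv(s, xs):
            return rhs(s, xs, u_delayed(s))

        k1 = deriv(t, x[i])
        k2 = deriv(t + dt / 2, x[i] + dt / 2 * k1)
        k3 = deriv(t + dt / 2, x[i] + dt / 2 * k2)
        k4 = deriv(t + dt, x[i] + dt * k3)
        x[i + 1] = x[i] + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x[i + 1])):
            raise RuntimeError(f"state became non-finite at t={t + dt:.6g}")
        if nlag:
            x_hist.append(x[i + 1])
        if obs_hist is not None:
            # midpoint step; the innovation interpolates the plant states
            # computed above and the stored observer history
            def dobs(s, xo):
                w = (s - t) / dt
                xs = (1 - w) * x[i] + w * x[i + 1]
                return mean_rhs(xo, u[i]) + K @ (xs - obs_hist(s - tau))

            k1o = dobs(t, obs_state)
            k2o = dobs(t + dt / 2, obs_state + dt / 2 * k1o)
            obs_state = obs_state + dt * k2o
            obs_hist.append(obs_state.copy())

    omega = ref = eps = None
    cert = getattr(controller, "cert", None)
    reference = getattr(controller, "reference", None)
    if cert is not None:
        cand = [base.subs_params(c) for c in cert.candidates]
        cand_specs = _jet_specs_in(base, cand)
        fn = sp.lambdify(
            list(base.states) + [jet_symbol(b, k) for b, k in cand_specs],
            cand, "numpy")
        bnd = binding or NoiseBinding.zero(base.fluctuations)
        omega = np.array([
            np.atleast_1d(fn(*xi, *[bnd.jets(ti, cand_specs)[sp_] for sp_ in cand_specs]))
            for ti, xi in zip(t_grid, x)], dtype=float)
        if reference is not None:
            ref = np.array([reference.value(ti) for ti in t_grid], dtype=float)
            eps = omega - ref
    return SimulationTrace(
        t=t_grid, x=x, u=u, omega=omega, reference=ref, eps_act=eps,
        metadata={"tau": tau, "dt": dt, "predictor": predictor.kind},
    )
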