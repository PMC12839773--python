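"""Oculomotor gaze-control example.

A single eye at distance d from a vertical screen tracks a point P = (X, Y)
in the screen frame.  By Listing's law the pupil pose reduces to a yaw angle
psi and a pitch angle phi; writing the generative model in screen coordinates
gives the control-affine stochastic model

    dX/dt      = v_psi (d^2 + (X - X0 - zeta_X)^2) / d + d zeta_X/dt
    dY/dt      = v_phi (d^2 + (Y - Y0 - zeta_Y)^2) / d + d zeta_Y/dt
    2 Ie dv_psi/dt = u_psi + zeta_psi          (yaw inertia doubled)
    Ie dv_phi/dt   = u_phi + zeta_phi

with eye inertia Ie, torques (u_psi, u_phi) and four smooth random
fluctuation channels.  The pair (X, Y) is a flat output with Brunovsky
indices (2, 2); the decoupling matrix is diagonal with entries
delta_X/(2 d Ie) and delta_Y/(d Ie), where delta = d^2 + (pos - centre)^2
>= d^2 > 0, so the feedback is singularity-free everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from . import flat_core, tracking
from .model import ControlAffineModel, NoiseBinding
from .reference import ReferenceTrajectory
from .smooth_random import sample_srf

__all__ = [
    "OculomotorParams",
    "build_oculomotor",
    "build_oculomotor_angles",
    "reference_sigmoid",
    "reference_quatrefoil",
    "reference_hypocycloid",
    "oculomotor_reference",
    "openloop_action",
    "bind_fluctuations",
    "run_tracking_experiment",
]

FLUCTUATION_NAMES = ("zeta_X", "zeta_Y", "zeta_psi", "zeta_phi")


@dataclass(frozen=True)
class OculomotorParams:
    """Eye/screen geometry and per-channel fluctuation configuration.

    Defaults: Ie = 4.032e-7 kg m^2, d = 10 m, projection centre at the
    origin, and band-limited noise with L = 8 s, wavelength 2 s on all four
    channels (hence r = 4 harmonics per channel).
    """

    Ie: float = 4.032e-7
    d: float = 10.0
    X0: float = 0.0
    Y0: float = 0.0
    noise_L: float = 8.0
    noise_lambda_w: float = 2.0
    alpha: float = 1e-5

    def __post_init__(self) -> None:
        if self.Ie <= 0 or self.d <= 0:
            raise ValueError("Ie and d must be strictly positive")


def build_oculomotor(params: OculomotorParams | None = None) -> ControlAffineModel:
    """The stochastic generative model in screen coordinates.

    First derivatives of zeta_X, zeta_Y enter the position equations
    additively; zeta_psi, zeta_phi enter the torque equations.  Setting all
    fluctuation jets to zero recovers the mean model.
    """
    params = params or OculomotorParams()
    xX, xY, xvpsi, xvphi = sp.symbols("xX xY xvpsi xvphi")
    upsi, uphi = sp.symbols("upsi uphi")
    Ie, d, X0, Y0 = sp.symbols("Ie d_screen X0 Y0")
    zX, zY = sp.Symbol("zeta_X"), sp.Symbol("zeta_Y")
    zX1, zY1 = sp.Symbol("zeta_X_d1"), sp.Symbol("zeta_Y_d1")
    zpsi, zphi = sp.Symbol("zeta_psi"), sp.Symbol("zeta_phi")
    delta_X = d**2 + (xX - X0 - zX) ** 2
    delta_Y = d**2 + (xY - Y0 - zY) ** 2
    return ControlAffineModel(
        states=(xX, xY, xvpsi, xvphi),
        inputs=(upsi, uphi),
        fluctuations=FLUCTUATION_NAMES,
        drift=(xvpsi * delta_X / d, xvphi * delta_Y / d, 0, 0),
        input_gain=sp.Matrix(
            [[0, 0], [0, 0], [1 / (2 * Ie), 0], [0, 1 / Ie]]
        ),
        noise=(zX1, zY1, zpsi / (2 * Ie), zphi / Ie),
        outputs=(xX, xY),
        params={Ie: params.Ie, d: params.d, X0: params.X0, Y0: params.Y0},
        name="oculomotor",
    )


def build_oculomotor_angles(params: OculomotorParams | None = None) -> ControlAffineModel:
    """Angle-form model (yaw/pitch states, Listing-law kinematics), noise-free.

    States (psi, phi, v_psi, v_phi); the screen position appears as output
    X = X0 + d tan(psi), Y = Y0 + d tan(phi).  Used as a change-of-variables
    oracle for the Cartesian model.
    """
    params = params or OculomotorParams()
    psi, phi, vpsi, vphi = sp.symbols("psi phi vpsi vphi")
    upsi, uphi = sp.symbols("upsi uphi")
    Ie, d, X0, Y0 = sp.symbols("Ie d_screen X0 Y0")
    return ControlAffineModel(
        states=(psi, phi, vpsi, vphi),
        inputs=(upsi, uphi),
        drift=(vpsi, vphi, 0, 0),
        input_gain=sp.Matrix([[0, 0], [0, 0], [1 / (2 * Ie), 0], [0, 1 / Ie]]),
        outputs=(X0 + d * sp.tan(psi), Y0 + d * sp.tan(phi)),
        params={Ie: params.Ie, d: params.d, X0: params.X0, Y0: params.Y0},
        name="oculomotor_angles",
    )


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

def reference_sigmoid(xl: float = 1.0, xh: float = 4.0, gamma: float = 4.0,
                      t_raise: float = 20.0, domain=(0.0, 80.0)) -> ReferenceTrajectory:
    """Smooth step (xh - xl)/2 (1 + tanh(gamma (t - t_raise))) + xl."""
    if xh <= xl:
        raise ValueError("need xh > xl")
    if gamma <= 0:
        raise ValueError("need gamma > 0")
    t = sp.Symbol("t")
    e = (xh - xl) / 2 * (1 + sp.tanh(gamma * (t - t_raise))) + xl
    return ReferenceTrajectory([e], t, max_order=2, domain=domain, name="sigmoid")


def reference_quatrefoil(a: float = 2.0) -> ReferenceTrajectory:
    """Quatrefoil X = 2a sin^2(t) cos(t), Y = 2a cos^2(t) sin(t); period 2 pi."""
    if a <= 0:
        raise ValueError("need a > 0")
    t = sp.Symbol("t")
    X = 2 * a * sp.sin(t) ** 2 * sp.cos(t)
    Y = 2 * a * sp.cos(t) ** 2 * sp.sin(t)
    return ReferenceTrajectory([X, Y], t, max_order=2,
                               domain=(0.0, float(2 * np.pi)), name="quatrefoil")


def reference_hypocycloid(a: float = 2.0, b: float = 6.0 / 5.0) -> ReferenceTrajectory:
    """Hypocycloid X = (a-b) cos t + b cos((a-b) t / b), and the sine
    counterpart for Y; closes after the least common period of the two
    angular arguments (6 pi for a=2, b=6/5)."""
    if not a > b > 0:
        raise ValueError("need a > b > 0")
    t = sp.Symbol("t")
    X = (a - b) * sp.cos(t) + b * sp.cos((a - b) * t / b)
    Y = (a - b) * sp.sin(t) - b * sp.sin((a - b) * t / b)
    return ReferenceTrajectory([X, Y], t, max_order=2,
                               domain=(0.0, float(6 * np.pi)), name="hypocycloid")


def oculomotor_reference(name: str) -> ReferenceTrajectory:
    """Two-channel reference by name: 'sigmoid', 'quatrefoil', 'hypocycloid'.

    The sigmoid pair uses the stated X-channel parameters (xl=1, xh=4,
    gamma=4, t_raise=20 s) and a later, lower rise on the Y channel.
    """
    if name == "sigmoid":
        t = sp.Symbol("t")
        eX = sp.Rational(3, 2) * (1 + sp.tanh(4 * (t - 20))) + 1
        eY = 1 * (1 + sp.tanh(4 * (t - 40))) + 1
        return ReferenceTrajectory([eX, eY], t, max_order=2, domain=(0.0, 80.0),
                                   name="sigmoid")
    if name == "quatrefoil":
        return reference_quatrefoil()
    if name == "hypocycloid":
        return reference_hypocycloid()
    raise ValueError(f"unknown reference {name!r}")


# ---------------------------------------------------------------------------
# flatness objects and experiments
# ---------------------------------------------------------------------------

def certify(model: ControlAffineModel) -> flat_core.FlatnessCertificate:
    return flat_core.brunovsky_analysis(model, [model.states[0], model.states[1]])


def openloop_action(params: OculomotorParams, reference: ReferenceTrajectory,
                    mode: str = "mean") -> tracking.OpenLoopController:
    """Open-loop torque law from the flat parametrisation with the flat
    output replaced by the reference (oracle mode also substitutes the true
    fluctuation jets)."""
    model = build_oculomotor(params)
    cert = certify(model)
    par = flat_core.functional_parametrisation(model, cert)
    return tracking.open_loop_controller(par, reference, mode=mode)


def bind_fluctuations(params: OculomotorParams, alpha: float, seed: int) -> NoiseBinding:
    """One smooth random function per channel; per-channel seeds derived
    deterministically from the master seed."""
    child = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    return NoiseBinding({
        name: sample_srf(params.noise_L, params.noise_lambda_w,
                         mode="standard", alpha=alpha, seed=int(s))
        for name, s in zip(FLUCTUATION_NAMES, child)
    })


def run_tracking_experiment(
    params: OculomotorParams | None = None,
    reference_name: str = "quatrefoil",
    gains: tracking.TrackingGains | None = None,
    alpha: float = 1e-5,
    seed: int = 0,
    mode: str = "oracle",
    t_span=None,
    dt: float = 1e-3,
    x0=None,
):
    """End-to-end tracking run: build the model, bind four smooth random
    fluctuation channels, synthesise the tracking controller, simulate, and
    report the trace plus summary metrics.

    Default initial conditions place the state exactly on the reference jets
    at t = 0.  Returns (trace, summary dict).
    """
    params = params or OculomotorParams()
    model = build_oculomotor(params)
    cert = certify(model)
    reference = oculomotor_reference(reference_name)
    gains = gains or tracking.TrackingGains.pole_placement(cert.kappas, pole=2.0)
    binding = bind_fluctuations(params, alpha, seed)
    if t_span is None:
        t_span = reference.domain
    controller = tracking.tracking_controller(model, cert, reference, gains, mode=mode)
    if x0 is None:
        x0 = reference_consistent_state(params, reference, t_span[0])
    trace = tracking.simulate_closed_loop(
        model, controller, binding, x0, t_span, dt,
        metadata={"seed": seed, "alpha": alpha, "reference": reference_name},
    )
    # singularity margin: delta >= d^2 > 0 along the whole path
    dX = params.d**2 + (trace.x[:, 0] - params.X0) ** 2
    dY = params.d**2 + (trace.x[:, 1] - params.Y0) ** 2
    assert np.all(dX >= params.d**2 - 1e-9) and np.all(dY >= params.d**2 - 1e-9)
    metrics = tracking.discrepancy_metrics(
        trace, tracking.RiskConfig(np.eye(2))
    )
    summary = {
        "reference": reference_name,
        "alpha": alpha,
        "seed": seed,
        "mode": mode,
        "harmonics_per_channel": binding.signals["zeta_X"].r,
        "rms_eps_act": float(np.sqrt((trace.eps_act**2).sum(axis=1).mean())),
        "max_eps_act": float(np.abs(trace.eps_act).max()),
        "risk": metrics.risk,
        "integrated_squared_error": metrics.integrated_squared_error,
    }
    return trace, summary


def reference_consistent_state(params: OculomotorParams,
                               reference: ReferenceTrajectory, t: float) -> np.ndarray:
    """Mean-model state lying exactly on the reference jets at time t:
    positions at the reference values, angular speeds matching the reference
    velocities through the Listing-law gain d/delta."""
    pos = reference.value(t, 0)
    vel = reference.value(t, 1)
    dX = params.d**2 + (pos[0] - params.X0) ** 2
    dY = params.d**2 + (pos[1] - params.Y0) ** 2
    return np.array([
        pos[0], pos[1],
        vel[0] * params.d / dX,
        vel[1] * params.d / dY,
    ])
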