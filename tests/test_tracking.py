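"""Tracking laws, closed-loop simulation, and discrepancy/risk metrics."""

import numpy as np
import pytest
import sympy as sp

import flatpath as fp
from flatpath.smooth_random import sample_srf

from conftest import companion_solution


class TestGains:
    @pytest.mark.parametrize(
        "kappa, pole, expected",
        [(2, 2.0, (4.0, 4.0)), (1, 3.5, (3.5,)), (3, 1.0, (1.0, 3.0, 3.0))],
    )
    def test_binomial_coefficients(self, kappa, pole, expected):
        assert fp.hurwitz_gains(kappa, pole) == pytest.approx(expected)

    def test_nonpositive_pole_rejected(self):
        with pytest.raises(ValueError):
            fp.hurwitz_gains(2, 0.0)

    def test_non_hurwitz_coefficients_rejected(self):
        with pytest.raises(ValueError, match="Hurwitz"):
            fp.TrackingGains(((-1.0, 2.0),))


class TestTrackingV:
    def test_on_reference_returns_feedforward(self):
        gains = fp.TrackingGains(((4.0, 4.0),))
        v = fp.tracking_v([[1.0, 0.5]], [[1.0, 0.5, -2.0]], gains)
        assert v == pytest.approx([-2.0])

    def test_pure_error_arithmetic(self):
        gains = fp.TrackingGains(((4.0, 4.0),))
        v = fp.tracking_v([[1.0, 0.0]], [[0.0, 0.0, 0.0]], gains)
        assert v == pytest.approx([-4.0])

    def test_jet_order_mismatch(self):
        gains = fp.TrackingGains(((4.0, 4.0),))
        with pytest.raises(ValueError, match="mismatch"):
            fp.tracking_v([[1.0]], [[0.0, 0.0, 0.0]], gains)


class TestErrorDynamics:
    def test_closed_loop_error_matches_matrix_exponential(self, concrete_simple):
        model, cert = concrete_simple
        t = sp.Symbol("t")
        ref = fp.ReferenceTrajectory([1 + sp.sin(t) / 2], t, max_order=2,
                                     domain=(0, 5), name="sine")
        gains = fp.TrackingGains.pole_placement(cert.kappas, 2.0)
        ctrl = fp.tracking_controller(model, cert, ref, gains, mode="mean")
        x0 = np.array([ref.value(0.0)[0] + 0.8, ref.value(0.0, 1)[0] - 0.3])
        trace = fp.simulate_closed_loop(model, ctrl, None, x0, (0, 5), 1e-3)
        e0 = np.array([0.8, -0.3])
        analytic = companion_solution(gains.coefficients[0], e0, trace.t)
        assert np.max(np.abs(trace.eps_act[:, 0] - analytic)) < 1e-6

    @pytest.mark.parametrize("pole", [1.0, 2.0, 5.0])
    def test_designed_pole_recovered(self, concrete_simple, pole):
        model, cert = concrete_simple
        ref = fp.ReferenceTrajectory.constant([1.0], max_order=2, domain=(0, 30))
        gains = fp.TrackingGains.pole_placement(cert.kappas, pole)
        # the double-pole envelope (1 + p t) e^{-p t} approaches a pure
        # exponential only for p t >> 1, so fit over a long horizon
        ctrl = fp.tracking_controller(model, cert, ref, gains, mode="mean")
        trace = fp.simulate_closed_loop(model, ctrl, None, [0.0, 0.0],
                                        (0, 25.0 / pole), 1e-3)
        fitted = fp.fit_decay_rate(trace)
        assert fitted == pytest.approx(pole, rel=0.10)

    def test_on_reference_start_stays_on_reference(self, concrete_simple):
        model, cert = concrete_simple
        t = sp.Symbol("t")
        ref = fp.ReferenceTrajectory([sp.cos(t)], t, max_order=2, domain=(0, 3))
        gains = fp.TrackingGains.pole_placement(cert.kappas, 2.0)
        ctrl = fp.tracking_controller(model, cert, ref, gains, mode="mean")
        x0 = [ref.value(0.0)[0], ref.value(0.0, 1)[0]]
        trace = fp.simulate_closed_loop(model, ctrl, None, x0, (0, 3), 1e-3)
        assert np.max(np.abs(trace.eps_act)) < 1e-6


class TestIntegratorOrder:
    def test_rk4_fourth_order_step_halving(self, concrete_simple):
        model, cert = concrete_simple
        ref = fp.ReferenceTrajectory.constant([1.0], max_order=2, domain=(0, 1))
        gains = fp.TrackingGains.pole_placement(cert.kappas, 2.0)
        ctrl = fp.tracking_controller(model, cert, ref, gains, mode="mean")

        def terminal(dt):
            tr = fp.simulate_closed_loop(model, ctrl, None, [0.3, 0.1], (0, 1), dt)
            return tr.x[-1]

        e1 = np.linalg.norm(terminal(4e-2) - terminal(1e-3))
        e2 = np.linalg.norm(terminal(2e-2) - terminal(1e-3))
        order = np.log2(e1 / e2)
        assert order > 3.5


class TestNoiseScaling:
    def test_mean_controller_error_scales_linearly_in_alpha(self):
        # linear internal force, so the steady fluctuation response is linear
        x1, x2 = sp.symbols("x1 x2")
        model = fp.simple_example(f_expr=-x1 - x2)
        cert = fp.brunovsky_analysis(model, [model.outputs[0]])
        ref = fp.ReferenceTrajectory.constant([0.5], max_order=2, domain=(0, 12))
        gains = fp.TrackingGains.pole_placement(cert.kappas, 2.0)
        ctrl = fp.tracking_controller(model, cert, ref, gains, mode="mean")
        steady = []
        for alpha in (1e-6, 1e-5, 1e-4):
            binding = fp.NoiseBinding({
                name: sample_srf(8, 2, alpha=alpha, seed=10 + i)
                for i, name in enumerate(model.fluctuations)
            })
            x0 = [0.5, 0.0]
            tr = fp.simulate_closed_loop(model, ctrl, binding, x0, (0, 12), 1e-3)
            sel = tr.t > 4.0
            steady.append(np.sqrt((tr.eps_act[sel] ** 2).mean()))
        r1 = steady[1] / steady[0]
        r2 = steady[2] / steady[1]
        assert r1 == pytest.approx(10.0, rel=0.15)
        assert r2 == pytest.approx(10.0, rel=0.15)


class TestDiscrepancyMetrics:
    def test_zero_error_gives_zero_metrics(self, concrete_simple):
        model, cert = concrete_simple
        t = np.linspace(0, 1, 101)
        omega = np.ones((101, 1))
        trace = fp.SimulationTrace(
            t=t, x=np.zeros((101, 2)), u=np.zeros((101, 1)),
            omega=omega, reference=omega.copy(), eps_act=omega - omega,
        )
        m = fp.discrepancy_metrics(trace, fp.RiskConfig(np.eye(1)))
        assert m.risk == 0.0 and m.integrated_squared_error == 0.0

    def test_constant_offset_closed_form_risk(self):
        T, c = 3.0, 0.7
        t = np.linspace(0, T, 601)
        eps = np.full((t.size, 1), c)
        trace = fp.SimulationTrace(
            t=t, x=np.zeros((t.size, 1)), u=np.zeros((t.size, 1)),
            omega=eps, reference=np.zeros_like(eps), eps_act=eps,
        )
        m = fp.discrepancy_metrics(trace, fp.RiskConfig(np.eye(1)))
        assert m.risk == pytest.approx(T * c**2 / 2, rel=1e-12)

    def test_precision_validation(self):
        with pytest.raises(ValueError):
            fp.RiskConfig(np.array([[1.0, 2.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            fp.RiskConfig(np.array([[-1.0]]))

    def test_tracking_beats_open_loop_beats_zero_action(self, concrete_simple):
        model, cert = concrete_simple
        par = fp.functional_parametrisation(model, cert)
        t = sp.Symbol("t")
        ref = fp.ReferenceTrajectory([1 + sp.sin(t) / 2], t, max_order=2,
                                     domain=(0, 6))
        gains = fp.TrackingGains.pole_placement(cert.kappas, 2.0)
        x0 = [ref.value(0.0)[0] + 0.5, ref.value(0.0, 1)[0]]
        risk_cfg = fp.RiskConfig(np.eye(1))
        risks = {}
        for name, ctrl in (
            ("tracking", fp.tracking_controller(model, cert, ref, gains, "mean")),
            ("open_loop", fp.open_loop_controller(par, ref, mode="mean")),
            ("zero", fp.ZeroController(m=1)),
        ):
            tr = fp.simulate_closed_loop(model, ctrl, None, x0, (0, 6), 1e-3,
                                         reference=ref, cert=cert)
            risks[name] = fp.discrepancy_metrics(tr, risk_cfg).risk
        assert risks["tracking"] < risks["open_loop"] < risks["zero"]


class TestTraceContainer:
    def test_trace_shape_validation(self):
        with pytest.raises(ValueError):
            fp.SimulationTrace(t=np.array([0.0, 1.0, 0.5]),
                               x=np.zeros((3, 1)), u=np.zeros((3, 1)))
        with pytest.raises(ValueError):
            fp.SimulationTrace(t=np.array([0.0, 1.0]),
                               x=np.zeros((3, 1)), u=np.zeros((3, 1)))

    def test_to_frame_columns(self, concrete_simple):
        model, cert = concrete_simple
        ref = fp.ReferenceTrajectory.constant([1.0], max_order=2, domain=(0, 1))
        gains = fp.TrackingGains.pole_placement(cert.kappas, 2.0)
        ctrl = fp.tracking_controller(model, cert, ref, gains, mode="mean")
        tr = fp.simulate_closed_loop(model, ctrl, None, [0, 0], (0, 0.2), 1e-2)
        df = tr.to_frame()
        for col in ("t", "x1", "x2", "u1", "omega1", "ref1", "eps_act1"):
            assert col in df.columns
        assert tr.metadata["pole"] == 2.0
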