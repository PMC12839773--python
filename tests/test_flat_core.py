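"""Flatness engine: certification, parametrisation, feedback, realisation, planning."""

import numpy as np
import pytest
import sympy as sp

import flatpath as fp
from flatpath.flat_core import CandidateRejected, generically_zero
from flatpath.model import jet_symbol


class TestBrunovskyAnalysis:
    def test_double_integrator_flat(self, double_integrator_objects):
        _, cert, _ = double_integrator_objects
        assert cert.kappas == (2,)
        assert cert.flat
        assert cert.decoupling == sp.Matrix([[1]])
        assert cert.drift == (sp.S.Zero,)

    def test_velocity_candidate_not_flat(self):
        m = fp.double_integrator()
        cert = fp.brunovsky_analysis(m, [m.states[1]])
        assert cert.kappas == (1,)
        assert cert.total_index == 1 != m.n
        assert not cert.flat

    def test_simple_example_generic_f(self):
        m = fp.simple_example()  # undefined symbolic f(x1, x2)
        cert = fp.brunovsky_analysis(m, [m.outputs[0]])
        assert cert.kappas == (2,)
        assert cert.flat

    def test_bergman_relative_degree_three(self):
        from flatpath.gencoords import build_bergman

        m = build_bergman()
        cert = fp.brunovsky_analysis(m, [m.states[0]])
        assert cert.kappas == (3,)
        assert cert.flat
        # no input leaks into the input-free chain
        u = m.inputs[0]
        assert all(u not in e.free_symbols for ch in cert.chains for e in ch)

    def test_oculomotor_diagonal_decoupling(self, oculomotor_objects):
        model, cert, _ = oculomotor_objects
        assert cert.kappas == (2, 2)
        assert cert.total_index == model.n == 4
        assert cert.flat
        assert cert.decoupling[0, 1] == 0 and cert.decoupling[1, 0] == 0

    def test_input_dependent_candidate_rejected(self):
        m = fp.double_integrator()
        with pytest.raises(CandidateRejected, match="endogenous"):
            fp.brunovsky_analysis(m, [m.states[0] + m.inputs[0]])

    def test_derivative_cap_rejection(self):
        m = fp.double_integrator()
        with pytest.raises(CandidateRejected, match="no input appeared"):
            fp.brunovsky_analysis(m, [sp.Integer(1)])

    def test_sum_kappa_never_exceeds_n(self, oculomotor_objects, double_integrator_objects):
        for objs in (oculomotor_objects, double_integrator_objects):
            model, cert = objs[0], objs[1]
            assert cert.total_index <= model.n
            assert cert.flat == (cert.total_index == model.n)


class TestFunctionalParametrisation:
    def test_deterministic_simple_example(self):
        m = fp.simple_example(stochastic=False)
        x1 = m.states[0]
        cert = fp.brunovsky_analysis(m, [x1])
        par = fp.functional_parametrisation(m, cert)
        w0, w1, w2 = (jet_symbol("omega1", k) for k in range(3))
        f = sp.Function("f")
        assert par.x_exprs == (w0, w1)
        assert sp.simplify(par.u_exprs[0] - (w2 - f(w0, w1))) == 0

    def test_stochastic_simple_example_matches_closed_form(self):
        m = fp.simple_example()
        cert = fp.brunovsky_analysis(m, [m.outputs[0]])
        par = fp.functional_parametrisation(m, cert)
        w0, w1, w2 = (jet_symbol("omega1", k) for k in range(3))
        zy, zy1, zy2 = (jet_symbol("zeta_y", k) for k in range(3))
        zx1, zx1d = jet_symbol("zeta_x1"), jet_symbol("zeta_x1", 1)
        zx2 = jet_symbol("zeta_x2")
        f = sp.Function("f")
        assert sp.simplify(par.x_exprs[0] - (w0 - zy)) == 0
        assert sp.simplify(par.x_exprs[1] - (w1 - zy1 - zx1)) == 0
        expected_u = w2 - f(w0 - zy, w1 - zy1 - zx1) - zy2 - zx1d - zx2
        assert sp.simplify(par.u_exprs[0] - expected_u) == 0

    def test_residuals_zero_for_all_certified_models(
        self, double_integrator_objects, oculomotor_objects
    ):
        cases = [double_integrator_objects, oculomotor_objects]
        m = fp.simple_example()
        cert = fp.brunovsky_analysis(m, [m.outputs[0]])
        cases.append((m, cert, fp.functional_parametrisation(m, cert)))
        for model, cert, par in cases:
            res = fp.verify_parametrisation(model, par)
            assert all(generically_zero(r) for r in res), (model.name, res)

    def test_corrupted_parametrisation_exposes_dropped_term(self):
        m = fp.simple_example()
        cert = fp.brunovsky_analysis(m, [m.outputs[0]])
        par = fp.functional_parametrisation(m, cert)
        zx2 = jet_symbol("zeta_x2")
        broken = fp.FunctionalParametrisation(
            certificate=par.certificate,
            x_exprs=par.x_exprs,
            u_exprs=(par.u_exprs[0] + zx2,),  # drop the -zeta_x2 compensation
            alpha_x=par.alpha_x,
            alpha_u=par.alpha_u,
        )
        res = fp.verify_parametrisation(m, broken)
        assert sp.simplify(res[0]) == 0
        assert sp.simplify(res[1] + zx2) == 0  # residual equals -zeta_x2 here


class TestLinearisingFeedback:
    def test_double_integrator_identity(self, double_integrator_objects):
        model, cert, _ = double_integrator_objects
        fb = fp.linearising_feedback(model, cert)
        u = fb(np.array([0.3, -1.2]), np.array([2.5]))
        assert u == pytest.approx([2.5])

    def test_closed_loop_flat_output_acceleration_equals_v(self, oculomotor_objects):
        # noise-free oculomotor under the exact linearising feedback with a
        # constant v: measured flat-output accelerations equal v
        model, cert, _ = oculomotor_objects
        mean = model.mean()
        mean_cert = fp.brunovsky_analysis(mean, [mean.states[0], mean.states[1]])
        fb = fp.linearising_feedback(mean, mean_cert)
        v_const = np.array([0.02, -0.01])

        class ConstV:
            jet_specs = []

            def __call__(self, t, x, jets=None):
                return fb(x, v_const)

        trace = fp.simulate_closed_loop(
            mean, ConstV(), None, [0.5, -0.2, 0.001, 0.002], (0, 2.0), 1e-3
        )
        # analytic omega-dd along the path: drift + decoupling @ u
        b = sp.Matrix(mean_cert.drift)
        A = mean_cert.decoupling
        expr = b + A * sp.Matrix(mean.inputs)
        fn = sp.lambdify(list(mean.states) + list(mean.inputs),
                         mean.subs_params(expr), "numpy")
        acc = np.array([np.asarray(fn(*x, *u)).ravel()
                        for x, u in zip(trace.x, trace.u)])
        assert np.max(np.abs(acc - v_const)) < 1e-6

    def test_singularity_guard(self):
        # model with state-dependent gain vanishing at x1 = 0
        x1, u = sp.symbols("x1 u")
        m = fp.ControlAffineModel(
            states=(x1,), inputs=(u,), drift=(0,),
            input_gain=sp.Matrix([[x1]]), name="degenerate")
        cert = fp.brunovsky_analysis(m, [x1])
        fb = fp.linearising_feedback(m, cert)
        with pytest.raises(fp.SingularDecouplingMatrix):
            fb(np.array([0.0]), np.array([1.0]))


class TestRealisation:
    def test_dimension_and_chain_structure(self, oculomotor_objects):
        model, cert, par = oculomotor_objects
        real = fp.brunovsky_realisation(cert, par)
        assert real.dim == cert.total_index == 4
        # two of the four equations are pure integrations
        pure = [e for e in real.rhs_exprs if e in real.z_symbols]
        assert len(pure) == 2

    def test_trajectory_equivalence_with_original(self, concrete_simple):
        model, cert = concrete_simple
        par = fp.functional_parametrisation(model, cert)
        real = fp.brunovsky_realisation(cert, par)
        u_path = lambda t: np.array([0.3 * np.sin(2 * t)])  # noqa: E731

        class OpenU:
            jet_specs = []

            def __call__(self, t, x, jets=None):
                return u_path(t)

        x0 = np.array([0.4, -0.1])
        trace = fp.simulate_closed_loop(model, OpenU(), None, x0, (0, 3.0), 1e-3)
        # matched initial chain state: omega = x1, omega' = x2
        t_grid, z = fp.tracking.simulate_chain(real, lambda t: u_path(t), None,
                                               x0, (0, 3.0), 1e-3)
        assert np.max(np.abs(z[:, 0] - trace.x[:, 0])) < 1e-6


class TestPointToPoint:
    def test_double_integrator_cubic(self, double_integrator_objects):
        model, cert, _ = double_integrator_objects
        ref = fp.plan_point_to_point(model, cert, [0, 0], [1, 0], 0.0, 1.0)
        t = np.linspace(0, 1, 11)
        assert np.allclose(ref.value(t, 0)[0], 3 * t**2 - 2 * t**3, atol=1e-12)

    def test_rest_to_rest_identity(self, double_integrator_objects):
        model, cert, _ = double_integrator_objects
        ref = fp.plan_point_to_point(model, cert, [0.7, 0], [0.7, 0], 0.0, 2.0)
        t = np.linspace(0, 2, 9)
        assert np.allclose(ref.value(t, 0)[0], 0.7)
        assert np.allclose(ref.value(t, 1)[0], 0.0, atol=1e-12)

    def test_open_loop_transfer_reaches_target(self, concrete_simple):
        model, cert = concrete_simple
        par = fp.functional_parametrisation(model, cert)
        x0, x1 = np.array([0.0, 0.0]), np.array([1.0, 0.0])
        ref = fp.plan_point_to_point(model, cert, x0, x1, 0.0, 1.5)
        ctrl = fp.open_loop_controller(par, ref, mode="mean")
        trace = fp.simulate_closed_loop(model, ctrl, None, x0, (0, 1.5), 1e-3)
        assert np.max(np.abs(trace.x[-1] - x1)) < 1e-6
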