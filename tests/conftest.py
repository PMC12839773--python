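import numpy as np
import pytest
import sympy as sp

import flatpath as fp
from flatpath import oculomotor as oc


@pytest.fixture(scope="session")
def concrete_simple():
    """Deterministic simple example with a concrete nonlinear internal force."""
    x1, x2 = sp.symbols("x1 x2")
    model = fp.simple_example(f_expr=-sp.sin(x1) - x2, stochastic=False)
    cert = fp.brunovsky_analysis(model, [x1])
    return model, cert


@pytest.fixture(scope="session")
def oculomotor_objects():
    model = oc.build_oculomotor()
    cert = oc.certify(model)
    par = fp.functional_parametrisation(model, cert)
    return model, cert, par


@pytest.fixture(scope="session")
def double_integrator_objects():
    model = fp.double_integrator()
    cert = fp.brunovsky_analysis(model, [model.states[0]])
    par = fp.functional_parametrisation(model, cert)
    return model, cert, par


def companion_solution(lams, e0, t_grid):
    """Matrix-exponential solution of e^(k) + sum_j lam_j e^(j) = 0."""
    from scipy.linalg import expm

    k = len(lams)
    A = np.zeros((k, k))
    A[:-1, 1:] = np.eye(k - 1)
    A[-1, :] = -np.asarray(lams)
    return np.array([(expm(A * t) @ e0)[0] for t in t_grid])
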