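import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

from ctmcexp import (
    GTRParams,
    gtr_rate_matrix,
    hky_rate_matrix,
    jc_rate_matrix,
    validate_rate_matrix,
)

HKY_PI = np.array([0.2, 0.2, 0.3, 0.3])
HKY_KAPPA = 2.15
GTR_R = np.array([0.5, 0.3, 0.6, 0.2, 0.3, 0.2])

# a non-reversible generator with a complex eigendecomposition
UNR = np.array(
    [
        [-4.0, 2.0, 1.0, 1.0],
        [0.0, -3.0, 2.0, 1.0],
        [1.0, 0.0, -3.0, 2.0],
        [2.0, 1.0, 1.0, -4.0],
    ]
)


@pytest.fixture(scope="session")
def jc4():
    return jc_rate_matrix(4)


@pytest.fixture(scope="session")
def hky():
    return hky_rate_matrix(HKY_PI, HKY_KAPPA)


@pytest.fixture(scope="session")
def gtr():
    return gtr_rate_matrix(GTRParams(r=GTR_R, pi=HKY_PI))


@pytest.fixture(scope="session")
def unr():
    return validate_rate_matrix(UNR)


def quadrature_integral(Q, t, a, b, c, d):
    """Adaptive quadrature of int_0^t p_ac(u) p_db(t-u) du (oracle)."""
    val, _ = quad(
        lambda u: expm(Q * u)[a, c] * expm(Q * (t - u))[d, b],
        0.0,
        t,
        epsabs=1e-12,
        epsrel=1e-12,
        limit=200,
    )
    return val
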