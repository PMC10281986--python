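import numpy as np
import pytest

from nucdeform.synthetic import (
    NcpGeometryParams,
    PerturbationSpec,
    generate_ideal_ncp,
    perturb,
)


@pytest.fixture(scope="session")
def params():
    return NcpGeometryParams()


@pytest.fixture(scope="session")
def ideal(params):
    """The canonical ideal particle (147 bp, positions -73..+73)."""
    return generate_ideal_ncp(params, di_position=-30)


@pytest.fixture(scope="session")
def small_params():
    """A reduced particle for expensive loops (31 bp, positions -15..+15)."""
    return NcpGeometryParams(n_bp=31)


@pytest.fixture(scope="session")
def small_ideal(small_params):
    return generate_ideal_ncp(small_params)


@pytest.fixture()
def bump_model(ideal, params):
    spec = PerturbationSpec(kind="bump", strand="strand_bottom", center=-53,
                            amplitude=5.0, halfwidth=2.0)
    return perturb(ideal, spec, params), spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230620)


def random_rotation(rng):
    """Uniform random proper rotation (QR of a Gaussian matrix, det-corrected)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
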