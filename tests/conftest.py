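import numpy as np
import pytest

from specpair.chem import build_ideal_chlorin
from specpair.motif import DimerGeometry, build_motif


@pytest.fixture(scope="session")
def ideal_chlorin():
    return build_ideal_chlorin("Zn")


@pytest.fixture(scope="session")
def stacked_motif():
    """A native-like pi-stacked C2 His-chlorin dimer motif."""
    return build_motif(-60.0, 90.0, 0.0, DimerGeometry(6.7, 3.5, 90.0, 0.0), "epsilon")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q
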