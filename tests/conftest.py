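import numpy as np
import pytest

from afcomp.materials import Environment, preset
from afcomp.microstructure import LamellaSpec, SpecimenSpec


@pytest.fixture(scope="session")
def env():
    return Environment()


@pytest.fixture(scope="session")
def matrix_params():
    return preset("SEP-matrix")


@pytest.fixture(scope="session")
def bundle_params():
    return preset("SEP-fiber-bundle")


@pytest.fixture(scope="session")
def lamella():
    return LamellaSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def random_states(rng, n=100, amp=0.08):
    """Random deformation gradients with J in a healthy range."""
    out = []
    while len(out) < n:
        F = np.eye(3) + amp * rng.standard_normal((3, 3))
        if 0.8 < np.linalg.det(F) < 1.3:
            out.append(F)
    return out
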