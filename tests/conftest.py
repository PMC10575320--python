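import numpy as np
import pytest

from helimc.fixtures import ideal_helix, two_helix_template
from helimc.model import DEFAULT_PARAMS


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def helix30():
    return ideal_helix(30)


@pytest.fixture(scope="session")
def bundle30():
    return two_helix_template(30, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_valid_chain(n, rng, p=DEFAULT_PARAMS):
    """Random conformation with every bond inside the FENE domain."""
    from helimc.fixtures import build_chain

    lengths = rng.uniform(p.r0 - 0.8 * p.R, p.r0 + 0.8 * p.R, n - 1)
    thetas = rng.uniform(0.4, np.pi - 0.4, max(n - 2, 0))
    taus = rng.uniform(-np.pi, np.pi, max(n - 3, 0))
    return build_chain(lengths, thetas, taus)


def rigid_motion(coords, rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(scale=5.0, size=3)
    return coords @ rot.T + shift
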