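import numpy as np
import pytest

from organoid_mech import build_lattice, dilute, place_cells
from organoid_mech.network import DilutionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def full_lattice_64():
    """The study's default 64-node triangular lattice, fully occupied."""
    return build_lattice(64)


@pytest.fixture(scope="session")
def default_network():
    """64 nodes, random dilution to p=0.9, 32 cells - a typical instance."""
    net = build_lattice(64)
    net = dilute(net, DilutionSpec(mode="random", p=0.9, seed=7))
    return place_cells(net, 32, seed=8)


@pytest.fixture(scope="session")
def tiny_lattice():
    """Smallest admissible lattice (4x3 columns = 12 nodes)."""
    return build_lattice(12)
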