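import numpy as np
import pytest

from xmecp import build_fixture, make_state
from xmecp.eht import EHTCalculator


@pytest.fixture(scope="session")
def h2():
    return build_fixture("h2", r=0.74)


@pytest.fixture(scope="session")
def ethylene():
    return build_fixture("ethylene")


@pytest.fixture(scope="session")
def azobenzene():
    return build_fixture("azobenzene", cnnc=180.0)


@pytest.fixture(scope="session")
def h2_states():
    gs = make_state("GS", 1, 1, [], n_orbitals=2)
    os1 = make_state("OS1", 1, 1, [("HOMO", "LUMO", "alpha")], n_orbitals=2)
    return gs, os1


@pytest.fixture(scope="session")
def ethylene_states(ethylene):
    calc = EHTCalculator(ethylene)
    norb = calc.basis.n_functions
    gs = make_state("GS", 6, 6, [], n_orbitals=norb)
    os1 = make_state("OS1", 6, 6, [("HOMO", "LUMO", "alpha")], n_orbitals=norb)
    return gs, os1


def rigid_transform(coords, seed=0):
    """A deterministic proper rotation + translation of (n,3) coordinates."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(size=3)
    return coords @ q.T + t
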