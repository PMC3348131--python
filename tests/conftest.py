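import numpy as np
import pytest

from ensemblepockets import fixtures as fx
from ensemblepockets.conformer_gen import build_constraints


@pytest.fixture(scope="session")
def helix_bundle():
    """300-atom ideal helix bundle (4 × 15 ALA residues)."""
    return fx.make_helix_bundle(seed=0)


@pytest.fixture(scope="session")
def helix_constraints(helix_bundle):
    return build_constraints(helix_bundle)


@pytest.fixture(scope="session")
def shell():
    """Open shell-cavity fixture with its analytic cavity volume."""
    return fx.make_shell_cavity(seed=0)


@pytest.fixture(scope="session")
def closed_shell():
    return fx.make_shell_cavity(aperture=0.0, seed=0)


@pytest.fixture(scope="session")
def slab():
    return fx.make_slab(seed=0)


@pytest.fixture(scope="session")
def two_cavity():
    return fx.make_two_cavity(seed=0)


@pytest.fixture(scope="session")
def shell_pockets(shell):
    from ensemblepockets.pocket_detect import detect_pockets

    return detect_pockets(shell[0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
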