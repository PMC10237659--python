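import numpy as np
import pytest

from symdock import fixtures, rpxscore


@pytest.fixture(scope="session")
def helix21():
    return fixtures.make_ideal_helix(21)


@pytest.fixture(scope="session")
def helix12():
    return fixtures.make_ideal_helix(12)


@pytest.fixture(scope="session")
def trimer(helix12):
    return fixtures.make_toy_oligomer(helix12, 3, 10.0)


@pytest.fixture(scope="session")
def tetramer(helix12):
    return fixtures.make_toy_oligomer(helix12, 4, 11.0)


@pytest.fixture(scope="session")
def synth_table():
    """Small synthetic hscore table shared across tests (seeded)."""
    return fixtures.make_synthetic_hscore(
        fixtures.FixtureSpec(seed=11, hscore_n_keys=20), n_levels=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
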