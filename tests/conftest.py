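import numpy as np
import pytest

import sagmetab as sm


@pytest.fixture(scope="session")
def catalog():
    return sm.fixture_catalog()


@pytest.fixture(scope="session")
def small_community(catalog):
    """A 2x25-genome seeded community used by several read-only tests."""
    cfg = sm.CommunityConfig(n_genomes_per_habitat=25, seed=42)
    return sm.simulate_community(cfg, catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
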