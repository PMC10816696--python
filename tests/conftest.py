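import numpy as np
import pytest

from ivoryid.synth import SyntheticRunConfig, make_toy_db


@pytest.fixture(scope="session")
def toy_config():
    return SyntheticRunConfig(seed=11)


@pytest.fixture(scope="session")
def toy_db(toy_config):
    """One toy database (6 species, 3 genera, 2 families) shared by all tests."""
    db, truth = make_toy_db(toy_config)
    return db, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
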