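import numpy as np
import pytest

from strongties import GeneratorConfig, generate_population
from strongties.indices import build_index_bundle


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(n=3000, seed=7)


@pytest.fixture(scope="session")
def population(default_config):
    """A moderate synthetic sample shared across read-only tests."""
    return generate_population(default_config)


@pytest.fixture(scope="session")
def indexed(population):
    """The same sample with the tie indices derived."""
    table, diag = build_index_bundle(population)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
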