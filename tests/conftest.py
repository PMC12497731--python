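import numpy as np
import pytest

from saltlax import (
    default_schema,
    default_simulation_config,
    generate_panel,
    load_fixture,
)


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_panel():
    """One deterministic synthetic panel (6 treatments x 5 replicates)."""
    return generate_panel(default_simulation_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
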