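import numpy as np
import pytest

from copdcea.mortality import LifeTable
from copdcea.params import DistributionSpec, ParameterTable, load_parameters


@pytest.fixture(scope="session")
def table():
    return load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return LifeTable.default()


@pytest.fixture(scope="session")
def fixed_table(table):
    """Every distribution degenerate at its base value (deterministic PSA)."""
    specs = {
        k: DistributionSpec.fixed(table[k].base_value) for k in table.keys()
    }
    return ParameterTable(specs, table.discount_rate, table.wtp)


@pytest.fixture(scope="session")
def trial_run():
    """The trial-horizon scenario at full replication count (shared)."""
    from copdcea.scenarios import run_scenario

    return run_scenario("trial_1y", seed=1)


@pytest.fixture(scope="session")
def base_run():
    """The 30-year base-case scenario at full replication count (shared)."""
    from copdcea.scenarios import run_scenario

    return run_scenario("base_case_30y", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
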