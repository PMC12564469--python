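import numpy as np
import pandas as pd
import pytest

import g4causal as g


@pytest.fixture(scope="session")
def shipped_spec():
    return g.default_spec()


@pytest.fixture(scope="session")
def shipped_dag(shipped_spec):
    return g.dag_from_edges(shipped_spec.nodes, shipped_spec.edges)


@pytest.fixture(scope="session")
def shipped_cpdag(shipped_dag):
    return g.dag_to_cpdag(shipped_dag)


@pytest.fixture(scope="session")
def small_dataset(shipped_spec):
    """A modest sample from the shipped ground-truth network."""
    return g.simulate_observations(shipped_spec, 1500, seed=20240901)


@pytest.fixture()
def fixture_config():
    return g.FixtureConfig()


@pytest.fixture(scope="session")
def genome_fixture():
    return g.make_genome_fixture(seed=7)


@pytest.fixture(scope="session")
def region_table(genome_fixture):
    return g.build_region_table(genome_fixture)
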