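import numpy as np
import pytest

from clonetrace import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """A 300-cell tracked population under default study conditions."""
    return simulate_population(SimConfig(tracked_lineages=300, seed=1))


@pytest.fixture(scope="session")
def mid_pop():
    """A larger population for genotyping/lineage recovery checks."""
    return simulate_population(SimConfig(tracked_lineages=500, seed=5, panel_ado_rate=0.1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
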