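import numpy as np
import pandas as pd
import pytest

from seedtox.seeds import SeedViabilityTable, enumerate_seed_space
from seedtox.synthetic import SimulationSpec, make_viability_table


@pytest.fixture(scope="session")
def all_seeds():
    return enumerate_seed_space()


@pytest.fixture(scope="session")
def constant_viability(all_seeds):
    """Every seed at exactly 100% viability in three pseudo cell lines."""
    per_line = pd.DataFrame(
        {f"line{i}": np.full(len(all_seeds), 100.0) for i in range(1, 4)},
        index=pd.Index(all_seeds, name="seed"),
    )
    return SeedViabilityTable(species="human", per_line=per_line)


@pytest.fixture(scope="session")
def synthetic_viability():
    return make_viability_table(SimulationSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
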