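import numpy as np
import pandas as pd
import pytest

import hologen as hg


@pytest.fixture(scope="session")
def small_config():
    return hg.SimulationConfig(
        n_sires=8,
        progeny_per_sire=10,
        pigs_per_pen=5,
        n_markers=300,
        n_otu=60,
        n_contemporary_groups=3,
        n_traits=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return hg.simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts():
    """Small OTU count table with a known sparsity pattern."""
    counts = pd.DataFrame(
        {
            "OTU1": [0, 0, 0],
            "OTU2": [400, 400, 400],
            "OTU3": [2000, 2000, 1000],
        },
        index=["s1", "s2", "s3"],
    )
    return hg.OtuCountTable(counts, stage="Wean")
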