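import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import CommunityTable
from ecoassembly.simulate import simulate_metadata, simulate_pool, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(rng, n_samples=6, n_otus=20, high=50):
    counts = rng.integers(0, high, size=(n_samples, n_otus))
    return CommunityTable(
        pd.DataFrame(
            counts,
            index=[f"S{i:02d}" for i in range(n_samples)],
            columns=[f"OTU_{j:04d}" for j in range(n_otus)],
        )
    )


@pytest.fixture
def small_table(rng):
    return make_table(rng)


@pytest.fixture(scope="session")
def yule_tree():
    return simulate_tree(60, seed=7)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated drift community shared across tests."""
    from ecoassembly.simulate import simulate_communities

    tree = simulate_tree(120, seed=11)
    pool = simulate_pool(120, seed=12)
    metadata = simulate_metadata(n_sites=6, seed=13)
    table, truth = simulate_communities(pool, tree, metadata, regime="drift",
                                        reads=3000, seed=14)
    return {"tree": tree, "pool": pool, "metadata": metadata,
            "table": table, "truth": truth}
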