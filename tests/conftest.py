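import numpy as np
import pytest

from szind import graphs, octane


@pytest.fixture(scope="session")
def atlas6():
    """All connected graphs on 1..6 vertices up to isomorphism (143)."""
    return graphs.connected_graph_atlas(6)


@pytest.fixture(scope="session")
def random_pool():
    """Seeded pool of random connected graphs, n up to 25."""
    rng = np.random.default_rng(20260925)
    pool = []
    for _ in range(60):
        n = int(rng.integers(5, 26))
        p = float(rng.uniform(0.12, 0.6))
        pool.append(graphs.random_connected_graph(n, p, rng))
    return pool


@pytest.fixture(scope="session")
def octane_records():
    return octane.octane_dataset()
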