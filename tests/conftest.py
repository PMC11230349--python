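import numpy as np
import pytest

import connsnr as cs


@pytest.fixture
def four_node_graph():
    """n=4, sigma=(1,1,2,2), edges {(1,2),(1,3),(3,4)} (1-based)."""
    adj = np.zeros((4, 4))
    for u, v in [(0, 1), (0, 2), (2, 3)]:
        adj[u, v] = adj[v, u] = 1
    return cs.BinaryConnectome(adjacency=adj), cs.make_planted_partition(4, 2)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic study cohort (seed 0) with its ground-truth partition."""
    return cs.simulate_fc_cohort(cs.SimConfig(seed=0))


@pytest.fixture(scope="session")
def planted_ga(planted_cohort):
    cohort, partition = planted_cohort
    return cs.group_average(cohort), partition


def random_graph_and_partition(rng, n_max=30, weighted=False):
    """Random small test instance for oracle comparisons."""
    n = int(rng.integers(4, n_max + 1))
    k = int(rng.integers(1, min(5, n) + 1))
    sigma = rng.integers(0, k, size=n)
    sigma[rng.permutation(n)[:k]] = np.arange(k)  # no empty community
    part = cs.Partition.from_labels(sigma)
    if weighted:
        m = rng.uniform(-1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return cs.WeightedConnectome(weights=m), part
    a = (rng.random((n, n)) < 0.4).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    return cs.BinaryConnectome(adjacency=a), part
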