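import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from wmnet import (
    ConnectivityMatrix,
    SimulationConfig,
    ThresholdGrid,
    WeightedGraph,
    generate_cohort,
)


def graph_from_weights(weights: np.ndarray, tau: float = 0.0) -> WeightedGraph:
    m = ConnectivityMatrix("toy", weights, [f"n{i}" for i in range(len(weights))])
    from wmnet import threshold_graph

    return threshold_graph(m, tau)


@pytest.fixture
def two_triangles() -> WeightedGraph:
    """Two disconnected unit-weight triangles on 6 nodes."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[a, b] = w[b, a] = 1.0
    return graph_from_weights(w)


@pytest.fixture
def unit_star() -> WeightedGraph:
    """Unit-weight star, centre node 0, N = 4."""
    w = np.zeros((4, 4))
    for leaf in (1, 2, 3):
        w[0, leaf] = w[leaf, 0] = 1.0
    return graph_from_weights(w)


@pytest.fixture(scope="session")
def small_null_cohort():
    """Null two-group cohort (no injected effects), reused where possible."""
    return generate_cohort(
        SimulationConfig(n_per_group=8, n_nodes=24, n_modules=3, seed=7)
    )


@pytest.fixture(scope="session")
def coarse_grid() -> ThresholdGrid:
    return ThresholdGrid(0.002, 0.008, 0.002)
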