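"""Thresholded weighted graphs over the consensus threshold grid.

Thresholds are absolute weight cutoffs on the connection-probability scale:
an edge survives at tau iff its weight is >= tau. Weights are retained, so
all downstream metrics are weighted. Edge sets are nested across the grid
(monotone non-increasing in tau) by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ConnectivityMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdGrid:
    """Evenly spaced absolute-weight thresholds, default 0.001..0.01 step 0.001."""

    start: float = 0.001
    stop: float = 0.01
    step: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValidationError(
                f"need 0 <= start < stop, got [{self.start}, {self.stop}]"
            )
        if self.step <= 0:
            raise ValidationError(f"step must be positive, got {self.step}")
        if len(self.values) < 2:
            raise ValidationError("threshold grid needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        taus = self.start + self.step * np.arange(n)
        return taus[taus <= self.stop + 1e-12]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class WeightedGraph:
    """Undirected weighted graph at one threshold; node labels preserved."""

    graph: nx.Graph
    threshold: float
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_labels:
            self.node_labels = [str(n) for n in self.graph.nodes]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(
            self.graph, nodelist=range(self.n_nodes), weight="weight"
        )


def threshold_graph(matrix: ConnectivityMatrix, tau: float) -> WeightedGraph:
    """Keep edges with weight >= tau (ties kept); weights unchanged."""
    if tau < 0:
        raise ValidationError(f"threshold must be nonnegative, got {tau}")
    w = matrix.weights
    g = nx.Graph()
    g.add_nodes_from(range(matrix.n_nodes))
    ii, jj = np.nonzero(np.triu(w, k=1) >= max(tau, np.finfo(float).tiny))
    g.add_weighted_edges_from(
        (int(i), int(j), float(w[i, j])) for i, j in zip(ii, jj)
    )
    if g.number_of_edges() == 0:
        logger.warning(
            "subject %s: threshold %g removes all edges", matrix.subject_id, tau
        )
    return WeightedGraph(g, tau, list(matrix.node_ids))


def grid_graphs(
    matrix: ConnectivityMatrix, grid: ThresholdGrid
) -> list[WeightedGraph]:
    """One graph per grid point, ordered by increasing tau (nested edge sets)."""
    return [threshold_graph(matrix, float(tau)) for tau in grid.values]
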