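"""Weighted global and regional topological attributes.

Conventions (frozen, documented in docs/methods.md):

* clustering — Onnela geometric-mean triangle form with weights normalized
  by the graph maximum; the toolkit standard for weighted brain networks.
* distances — edge length 1/w, the dominant convention for
  probability-weighted connectomes; disconnected pairs are excluded from
  the characteristic path length (their count is reported) and contribute
  0 to nodal efficiency.
* modularity — Newman weighted modularity, maximized by Louvain with
  seeded restarts.
* small-worldness — sigma = (C/C_rand)/(L/L_rand) against degree-preserving
  (Maslov–Sneppen) rewired nulls with the weight multiset permuted onto the
  rewired topology; a cluster-correction flag additionally requires C to
  exceed the null 95th percentile, guarding against calling a near-random
  graph small-world.
* hubness — integer 0..4: one point each for strength in the top 20%,
  weighted betweenness in the top 20%, weighted clustering in the bottom
  20%, and nodal efficiency in the top 20% (ties included on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .graphs import WeightedGraph
from .io import ValidationError

HUB_PERCENTILE = 0.80  # top-20% / bottom-20% cutoffs for the hubness score


@dataclass
class GlobalMetrics:
    """Whole-network attributes of one thresholded graph."""

    cp: float  # mean weighted clustering coefficient
    lp: float  # weighted characteristic path length (1/w edge lengths)
    q: float  # Louvain-optimized Newman weighted modularity
    sigma: float  # small-worldness (C/C_rand)/(L/L_rand)
    sigma_cluster_ok: bool  # clustering genuinely exceeds the null level
    n_null: int
    null_summary: dict[str, float]
    n_excluded_pairs: int = 0  # disconnected ordered pairs excluded from lp


@dataclass
class NodalMetrics:
    """Per-node attributes; arrays aligned with ``node_labels``."""

    node_labels: list[str]
    enod: np.ndarray
    strength: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    hubness: np.ndarray


def clustering_coefficient(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """Per-node Onnela weighted clustering and its mean over all nodes.

    C_i = (1/(k_i(k_i-1))) sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} with
    w' = w / max(w); isolated and degree-1 nodes get 0.
    """
    if g.n_nodes == 0:
        raise ValidationError("clustering of an empty graph is undefined")
    if g.n_edges == 0:
        return np.zeros(g.n_nodes), 0.0
    cdict = nx.clustering(g.graph, weight="weight")
    per_node = np.array([cdict[i] for i in range(g.n_nodes)], dtype=float)
    return per_node, float(per_node.mean())


def shortest_path_lengths(g: WeightedGraph) -> np.ndarray:
    """All-pairs weighted distances with edge length 1/w; inf if disconnected."""
    w = g.weight_matrix()
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def characteristic_path_length(
    g: WeightedGraph, dist: np.ndarray | None = None
) -> tuple[float, int]:
    """Mean distance over connected ordered pairs; also the excluded-pair count."""
    if g.n_nodes < 2:
        raise ValidationError("path length needs at least 2 nodes")
    d = shortest_path_lengths(g) if dist is None else dist
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int(off.sum() - finite.sum())
    if not finite.any():
        raise ValidationError("no connected pair of nodes")
    return float(d[finite].mean()), n_excluded


def nodal_efficiency(
    g: WeightedGraph, dist: np.ndarray | None = None
) -> np.ndarray:
    """E_nod(i) = mean over j != i of 1/d_ij, with 1/inf = 0."""
    if g.n_nodes < 2:
        raise ValidationError("nodal efficiency needs at least 2 nodes")
    d = shortest_path_lengths(g) if dist is None else dist
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=1) / (g.n_nodes - 1)


def modularity_q(g: WeightedGraph, partition: list[set[int]]) -> float:
    """Newman weighted modularity of a given partition."""
    return float(
        nx.community.modularity(g.graph, partition, weight="weight")
    )


def modularity_louvain(
    g: WeightedGraph, seed: int = 0, restarts: int = 20
) -> tuple[list[set[int]], float]:
    """Best Louvain partition over seeded restarts; ties by first found."""
    if g.n_edges == 0:
        raise ValidationError("modularity of an edgeless graph is undefined")
    best_q = -np.inf
    best: list[set[int]] = []
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            g.graph, weight="weight", seed=seed + r
        )
        q = modularity_q(g, comms)
        if q > best_q:
            best_q, best = q, [set(c) for c in comms]
    return best, float(best_q)


def _rewired_null(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """Degree-preserving rewiring; weight multiset permuted onto new edges."""
    m = g.n_edges
    h = nx.Graph()
    h.add_nodes_from(range(g.n_nodes))
    h.add_edges_from(g.graph.edges())
    if m >= 2:
        nx.double_edge_swap(
            h,
            nswap=10 * m,
            max_tries=200 * m + 100,
            seed=int(rng.integers(2**31 - 1)),
        )
    weights = np.array(
        [d["weight"] for _, _, d in g.graph.edges(data=True)], dtype=float
    )
    perm = rng.permutation(m)
    for (u, v), k in zip(h.edges(), perm):
        h[u][v]["weight"] = float(weights[k])
    return WeightedGraph(h, g.threshold, list(g.node_labels))


def small_worldness(
    g: WeightedGraph, n_null: int = 100, seed: int = 0
) -> tuple[float, bool, dict[str, float]]:
    """Small-worldness sigma against a rewired null ensemble.

    sigma = (C_p/C_rand)/(L_p/L_rand), C_rand/L_rand being null-ensemble
    means. ``cluster_ok`` is True iff C_p exceeds the null 95th percentile.
    """
    if n_null < 1:
        raise ValidationError("n_null must be at least 1")
    comps = list(nx.connected_components(g.graph))
    if not comps or max(len(c) for c in comps) < 0.9 * g.n_nodes:
        raise ValidationError(
            "largest connected component covers < 90% of nodes; "
            "sigma undefined at this threshold"
        )
    rng = np.random.default_rng(seed)
    _, cp = clustering_coefficient(g)
    lp, _ = characteristic_path_length(g)
    c_nulls = np.empty(n_null)
    l_nulls = np.empty(n_null)
    for k in range(n_null):
        null = _rewired_null(g, rng)
        _, c_nulls[k] = clustering_coefficient(null)
        l_nulls[k], _ = characteristic_path_length(null)
    c_rand, l_rand = float(c_nulls.mean()), float(l_nulls.mean())
    if c_rand <= 0 or l_rand <= 0:
        raise ValidationError("degenerate null ensemble (zero C or L)")
    sigma = (cp / c_rand) / (lp / l_rand)
    cluster_ok = bool(cp > np.quantile(c_nulls, 0.95))
    summary = {
        "c_rand_mean": c_rand,
        "c_rand_sd": float(c_nulls.std(ddof=1)) if n_null > 1 else 0.0,
        "l_rand_mean": l_rand,
        "l_rand_sd": float(l_nulls.std(ddof=1)) if n_null > 1 else 0.0,
    }
    return float(sigma), cluster_ok, summary


def strength(g: WeightedGraph) -> np.ndarray:
    return g.weight_matrix().sum(axis=1)


def weighted_betweenness(g: WeightedGraph) -> np.ndarray:
    """Betweenness with 1/w edge lengths (high weight = short edge)."""
    h = g.graph.copy()
    for u, v, d in h.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    bdict = nx.betweenness_centrality(h, weight="length", normalized=True)
    return np.array([bdict[i] for i in range(g.n_nodes)], dtype=float)


def _top_mask(values: np.ndarray, pct: float = HUB_PERCENTILE) -> np.ndarray:
    """Membership of the top-(1-pct) set, ties at the cutoff included.

    When every value is identical all nodes qualify; when the cutoff
    collapses onto the minimum (heavy ties at the bottom, e.g. a star's
    leaves), inclusion becomes strict so the criterion stays discriminative.
    """
    if _all_equal(values):
        return np.ones(len(values), dtype=bool)
    cut = np.quantile(values, pct)
    if cut == values.min():
        return values > cut
    return values >= cut


def _bottom_mask(values: np.ndarray, pct: float = 1 - HUB_PERCENTILE) -> np.ndarray:
    if _all_equal(values):
        return np.ones(len(values), dtype=bool)
    cut = np.quantile(values, pct)
    if cut == values.max():
        return values < cut
    return values <= cut


def _all_equal(values: np.ndarray) -> bool:
    return np.ptp(values) <= 1e-12 * max(1.0, float(np.abs(values).max()))


def hubness_score(
    g: WeightedGraph,
    *,
    strength_vals: np.ndarray | None = None,
    betweenness_vals: np.ndarray | None = None,
    clustering_vals: np.ndarray | None = None,
    enod_vals: np.ndarray | None = None,
) -> np.ndarray:
    """Composite hub score 0..4 (ties at a percentile cutoff all included)."""
    if g.n_nodes < 5:
        raise ValidationError("hubness needs at least 5 nodes")
    s = strength(g) if strength_vals is None else strength_vals
    b = weighted_betweenness(g) if betweenness_vals is None else betweenness_vals
    c = (
        clustering_coefficient(g)[0]
        if clustering_vals is None
        else clustering_vals
    )
    e = nodal_efficiency(g) if enod_vals is None else enod_vals
    score = np.zeros(g.n_nodes, dtype=int)
    score += _top_mask(s)
    score += _top_mask(b)
    score += _bottom_mask(c)
    score += _top_mask(e)
    return score


def compute_all(
    g: WeightedGraph, seed: int = 0, n_null: int = 100, restarts: int = 20
) -> tuple[GlobalMetrics, NodalMetrics]:
    """All global and nodal attributes of one graph; deterministic given seed."""
    if g.n_edges == 0:
        raise ValidationError("metrics of an edgeless graph are undefined")
    dist = shortest_path_lengths(g)
    c_per_node, cp = clustering_coefficient(g)
    lp, n_excl = characteristic_path_length(g, dist)
    _, q = modularity_louvain(g, seed=seed, restarts=restarts)
    sigma, cluster_ok, null_summary = small_worldness(g, n_null, seed)
    enod = nodal_efficiency(g, dist)
    s = strength(g)
    b = weighted_betweenness(g)
    hub = hubness_score(
        g,
        strength_vals=s,
        betweenness_vals=b,
        clustering_vals=c_per_node,
        enod_vals=enod,
    )
    glob = GlobalMetrics(
        cp=cp,
        lp=lp,
        q=q,
        sigma=sigma,
        sigma_cluster_ok=cluster_ok,
        n_null=n_null,
        null_summary=null_summary,
        n_excluded_pairs=n_excl,
    )
    nodal = NodalMetrics(
        node_labels=list(g.node_labels),
        enod=enod,
        strength=s,
        betweenness=b,
        clustering=c_per_node,
        hubness=hub,
    )
    return glob, nodal
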