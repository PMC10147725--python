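"""Independent brute-force oracles for graph quantities.

Deliberately naive implementations (dynamic programming, exhaustive
enumeration, direct double sums, union-find) kept separate from the
library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall_oracle(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths over edge lengths 1/w, by dynamic programming."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def onnela_clustering_oracle(weights: np.ndarray) -> np.ndarray:
    """Per-node geometric-mean triangle clustering by exhaustive triples."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    w = weights / wmax
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if weights[j, h] > 0:
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * total / (k * (k - 1))
    return c


def modularity_oracle(
    weights: np.ndarray, communities: list[set[int]]
) -> float:
    """Newman weighted modularity by the direct double sum."""
    label = {}
    for ci, comm in enumerate(communities):
        for node in comm:
            label[node] = ci
    s = weights.sum(axis=1)
    two_m = weights.sum()
    q = 0.0
    n = weights.shape[0]
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += weights[i, j] - s[i] * s[j] / two_m
    return q / two_m


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_oracle(
    edges: list[tuple[int, int]], n_nodes: int
) -> list[set[int]]:
    """Edge-index components of an edge list, by union-find over nodes."""
    uf = UnionFind(n_nodes)
    for i, j in edges:
        uf.union(i, j)
    comps: dict[int, set[int]] = {}
    for k, (i, j) in enumerate(edges):
        comps.setdefault(uf.find(i), set()).add(k)
    return sorted(comps.values(), key=len, reverse=True)


def random_weighted_matrix(
    rng: np.random.Generator, n: int, density: float = 0.5
) -> np.ndarray:
    """Random symmetric nonnegative matrix with zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    return w + w.T
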