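"""Network-based statistic (NBS) for edge-level group inference.

Edge-wise GLM t-tests (group + covariates) are thresholded at a primary
alpha (one-tailed), connected components of the surviving edges are
extracted, and each observed component's size (number of links) is referred
to the permutation null distribution of the maximum component size,
controlling family-wise error. Permutations follow the same Freedman–Lane
residual scheme as the feature-level GLM. Edges are only testable when
present (nonzero) in at least half the subjects of each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .inference import _design
from .io import Cohort, ValidationError

TAILS = ("patient>control", "control>patient")


@dataclass
class NBSComponent:
    edges: list[tuple[str, str]]  # node labels
    size: int  # number of links
    fwe_p: float


@dataclass
class NBSResult:
    tail: str
    alpha_primary: float
    n_perm: int
    components: list[NBSComponent] = field(default_factory=list)
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    n_tested_edges: int = 0

    @property
    def min_fwe_p(self) -> float:
        return min((c.fwe_p for c in self.components), default=1.0)


def _edge_data(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack upper-triangle weights: (n_subjects × n_edges), + index arrays."""
    n = len(cohort.node_ids)
    iu = np.triu_indices(n, k=1)
    y = np.stack(
        [cohort.matrices[sid].weights[iu] for sid in cohort.subject_ids]
    )
    return y, iu[0], iu[1]


def _presence_mask(y: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Testable edges: nonzero in >= 50% of subjects in each group."""
    is_pat = group == "patient"
    pat_ok = (y[is_pat] > 0).mean(axis=0) >= 0.5
    con_ok = (y[~is_pat] > 0).mean(axis=0) >= 0.5
    return pat_ok & con_ok


def edgewise_stats(
    cohort: Cohort,
    covariates: np.ndarray | None = None,
    tail: str = "patient>control",
) -> dict:
    """Per-edge GLM t-statistics and one-tailed p-values on testable edges."""
    if tail not in TAILS:
        raise ValidationError(f"tail must be one of {TAILS}")
    group = cohort.groups()
    y, ei, ej = _edge_data(cohort)
    mask = _presence_mask(y, group)
    if not mask.any():
        raise ValidationError("no testable edges after the presence mask")
    x, _ = _design(group, covariates)
    t = _edge_t(x, y[:, mask])
    dof = x.shape[0] - x.shape[1]
    signed = t if tail == "patient>control" else -t
    p = stats.t.sf(signed, dof)
    return {
        "edge_i": ei[mask],
        "edge_j": ej[mask],
        "t": t,
        "p": p,
        "dof": dof,
        "mask": mask,
    }


def _edge_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Group t-statistic for each column of y (vectorized GLM)."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 1e-300))
    return beta[0] / se


def suprathreshold_components(
    edge_i: np.ndarray,
    edge_j: np.ndarray,
    p: np.ndarray,
    alpha_primary: float = 0.05,
    n_nodes: int | None = None,
) -> list[list[int]]:
    """Connected components of the graph of edges with p < alpha_primary.

    Returns, per component, the indices into the edge arrays; sorted by
    component size (number of links), largest first.
    """
    keep = np.nonzero(p < alpha_primary)[0]
    if keep.size == 0:
        return []
    n = int(n_nodes or (max(edge_i.max(), edge_j.max()) + 1))
    data = np.ones(keep.size)
    adj = csr_array(
        (data, (edge_i[keep], edge_j[keep])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[edge_i[keep]]
    comps: dict[int, list[int]] = {}
    for idx, c in zip(keep, comp_of_edge):
        comps.setdefault(int(c), []).append(int(idx))
    return sorted(comps.values(), key=len, reverse=True)


def _max_component_size(
    edge_i: np.ndarray, edge_j: np.ndarray, p: np.ndarray,
    alpha: float, n_nodes: int,
) -> int:
    comps = suprathreshold_components(edge_i, edge_j, p, alpha, n_nodes)
    return len(comps[0]) if comps else 0


def nbs_test(
    cohort: Cohort,
    covariates: np.ndarray | None = None,
    alpha_primary: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "patient>control",
) -> NBSResult:
    """Full NBS: observed components + max-size permutation null."""
    group = cohort.groups()
    if min((group == "patient").sum(), (group == "control").sum()) < 2:
        raise ValidationError("need at least 2 subjects per group")
    obs = edgewise_stats(cohort, covariates, tail)
    ei, ej, dof = obs["edge_i"], obs["edge_j"], obs["dof"]
    n_nodes = len(cohort.node_ids)
    comps = suprathreshold_components(ei, ej, obs["p"], alpha_primary, n_nodes)

    # Freedman–Lane null: permute covariate-reduced residuals of every edge
    y, _, _ = _edge_data(cohort)
    y = y[:, obs["mask"]]
    x, z = _design(group, covariates)
    gamma, *_ = np.linalg.lstsq(z, y, rcond=None)
    fitted = z @ gamma
    resid = y - fitted
    t_crit = stats.t.isf(alpha_primary, dof)  # p < alpha  <=>  signed t > crit
    sign = 1.0 if tail == "patient>control" else -1.0
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(y.shape[0])
        t_b = _edge_t(x, fitted + resid[perm])
        supra = sign * t_b > t_crit
        keep = np.nonzero(supra)[0]
        if keep.size == 0:
            null_max[b] = 0
            continue
        null_max[b] = _max_component_size(
            ei, ej, np.where(supra, 0.0, 1.0), 0.5, n_nodes
        )
    labels = cohort.node_ids
    components = []
    for comp in comps:
        size = len(comp)
        fwe_p = (1.0 + np.sum(null_max >= size)) / (1.0 + n_perm)
        components.append(
            NBSComponent(
                edges=[(labels[ei[k]], labels[ej[k]]) for k in comp],
                size=size,
                fwe_p=float(fwe_p),
            )
        )
    return NBSResult(
        tail=tail,
        alpha_primary=alpha_primary,
        n_perm=n_perm,
        components=components,
        null_max_sizes=null_max,
        n_tested_edges=int(obs["mask"].sum()),
    )


def nbs_both_tails(
    cohort: Cohort,
    covariates: np.ndarray | None = None,
    alpha_primary: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict[str, NBSResult]:
    """Run both directions; the contrast of interest is unknown a priori."""
    return {
        tail: nbs_test(cohort, covariates, alpha_primary, n_perm, seed, tail)
        for tail in TAILS
    }
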