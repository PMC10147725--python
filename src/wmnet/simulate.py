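"""Synthetic connectome cohorts with injectable group contrasts.

Control networks are weighted planted-partition graphs: nodes are split
into modules, within-module node pairs are connected with probability
``p_within`` and carry log-normal weights centred well above the threshold
grid, between-module pairs with probability ``p_between`` and weaker
weights. Patient networks apply configurable effects on top of the same
generating law:

* ``effect_modularity`` — shrinks the log-weight contrast between within-
  and between-module edges toward its midpoint, lowering modularity Q.
* ``effect_sigma`` — randomly rewires a fraction of edges, destroying
  triangles and lowering clustering and hence small-worldness sigma.
* ``effect_nodes`` — multiplies all weights incident to chosen nodes,
  raising (multiplier > 1) their nodal efficiency.
* ``clinical_coupling`` — makes a named clinical score a linear-Gaussian
  function of a per-subject network summary, for correlation analyses.

Reproducibility: one master seed; the per-subject stream for subject ``k``
of group ``g`` (control = 0, patient = 1) is
``numpy.random.SeedSequence((seed, g, k))``, so enlarging a cohort never
reshuffles existing subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import ThresholdGrid, threshold_graph
from .io import (
    AtlasTable,
    Cohort,
    ConnectivityMatrix,
    SubjectRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: clinical score laws for patients (mean, sd), matching a dependence cohort
CLINICAL_LAWS = {
    "bprs_total": (42.8, 11.04),
    "anxiety_depression": (13.0, 3.57),
    "lack_of_vitality": (8.43, 2.88),
    "thinking_disorder": (7.03, 2.33),
    "activity": (7.3, 3.24),
    "hostility_suspicion": (7.0, 2.99),
    "hama": (22.39, 8.60),
}

#: covariate laws shared by both groups (group-matched in expectation)
COVARIATE_LAWS = {"age": (34.0, 9.0), "education": (13.4, 3.9), "ftnd": (5.5, 2.2)}


@dataclass
class ClinicalCoupling:
    """score = intercept + coefficient * metric + Normal(0, noise_sd)."""

    score: str = "bprs_total"
    metric: str = "mean_weight"  # or "strength_sum"
    coefficient: float = 0.0
    noise_sd: float = 1.0
    intercept: float | None = None  # default: the score's tabulated mean


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated two-group cohort."""

    n_per_group: int = 46
    n_nodes: int = 90
    n_modules: int = 6
    p_within: float = 0.85
    p_between: float = 0.15
    # log-normal weight laws: exp(Normal(mu, s)), clipped into [0, 1].
    # Chosen so control networks are small-world (sigma > 1 with the
    # cluster check passing) and stay connected across the threshold grid,
    # while the grid still prunes weak between-module edges progressively.
    mu_within: float = float(np.log(0.02))
    s_within: float = 0.3
    mu_between: float = float(np.log(0.008))
    s_between: float = 0.3
    effect_modularity: float = 0.0
    effect_sigma: float = 0.0
    effect_nodes: list[tuple[int, float]] = field(default_factory=list)
    clinical_coupling: ClinicalCoupling | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.n_per_group < 3:
            raise ValidationError("n_per_group must be at least 3")
        if self.n_nodes < self.n_modules:
            raise ValidationError("more modules than nodes")
        if not 0.0 <= self.effect_sigma <= 1.0:
            raise ValidationError("effect_sigma is a fraction in [0, 1]")
        if not 0.0 <= self.effect_modularity <= 1.0:
            raise ValidationError("effect_modularity is a fraction in [0, 1]")
        for node, mult in self.effect_nodes:
            if mult <= 0:
                raise ValidationError(f"node multiplier must be > 0, got {mult}")
            if not 0 <= node < self.n_nodes:
                raise ValidationError(f"effect node {node} out of range")


def _module_labels(n_nodes: int, n_modules: int) -> np.ndarray:
    """Near-even contiguous split of nodes into modules."""
    sizes = [len(b) for b in np.array_split(np.arange(n_nodes), n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


def _patient_mus(cfg: SimulationConfig) -> tuple[float, float]:
    """Shrink the within/between log-weight contrast by effect_modularity."""
    mid = 0.5 * (cfg.mu_within + cfg.mu_between)
    half = 0.5 * (cfg.mu_within - cfg.mu_between) * (1.0 - cfg.effect_modularity)
    return mid + half, mid - half


def _simulate_matrix(
    cfg: SimulationConfig, rng: np.random.Generator, patient: bool
) -> np.ndarray:
    labels = _module_labels(cfg.n_nodes, cfg.n_modules)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(cfg.n_nodes, k=1)
    within = same[iu]
    p_edge = np.where(within, cfg.p_within, cfg.p_between)
    present = rng.random(len(p_edge)) < p_edge
    mu_w, mu_b = (
        _patient_mus(cfg) if patient else (cfg.mu_within, cfg.mu_between)
    )
    mu = np.where(within, mu_w, mu_b)
    s = np.where(within, cfg.s_within, cfg.s_between)
    weights = np.where(present, np.exp(rng.normal(mu, s)), 0.0)
    weights = np.clip(weights, 0.0, 1.0)
    w = np.zeros((cfg.n_nodes, cfg.n_nodes))
    w[iu] = weights
    w = w + w.T

    if patient and cfg.effect_sigma > 0:
        w = _rewire_fraction(w, cfg.effect_sigma, rng)
    if patient and cfg.effect_nodes:
        for node, mult in cfg.effect_nodes:
            w[node, :] *= mult
            w[:, node] *= mult
            w[node, node] = 0.0
        w = np.clip(w, 0.0, 1.0)
    return w


def _rewire_fraction(
    w: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Move a fraction of edges to uniformly random absent node pairs."""
    w = w.copy()
    n = w.shape[0]
    ii, jj = np.nonzero(np.triu(w, k=1))
    m = len(ii)
    k = int(round(fraction * m))
    if k == 0:
        return w
    pick = rng.choice(m, size=k, replace=False)
    for idx in pick:
        i, j = int(ii[idx]), int(jj[idx])
        weight = w[i, j]
        w[i, j] = w[j, i] = 0.0
        for _ in range(100):
            a, b = rng.integers(0, n, size=2)
            if a != b and w[a, b] == 0.0:
                w[a, b] = w[b, a] = weight
                break
        else:  # pragma: no cover - dense-graph fallback
            w[i, j] = w[j, i] = weight
    return w


def _subject_metric(w: np.ndarray, name: str) -> float:
    iu = np.triu_indices(w.shape[0], k=1)
    if name == "mean_weight":
        return float(w[iu].mean())
    if name == "strength_sum":
        return float(w.sum() / 2.0)
    raise ValidationError(f"unknown coupling metric {name!r}")


def default_atlas(n_nodes: int, n_modules: int) -> AtlasTable:
    """Synthetic atlas: alternating hemispheres, module index as subnetwork."""
    labels = _module_labels(n_nodes, n_modules)
    return AtlasTable(
        pd.DataFrame(
            {
                "node_id": [f"n{i:03d}" for i in range(n_nodes)],
                "region_name": [f"region_{i:03d}" for i in range(n_nodes)],
                "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(n_nodes)],
                "subnetwork": [f"M{m}" for m in labels],
            }
        )
    )


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate a two-group cohort; fully reproducible from ``cfg.seed``."""
    atlas = default_atlas(cfg.n_nodes, cfg.n_modules)
    node_ids = atlas.node_ids
    records: list[SubjectRecord] = []
    matrices: dict[str, ConnectivityMatrix] = {}
    for gi, group in enumerate(("control", "patient")):
        patient = group == "patient"
        for k in range(cfg.n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence((cfg.seed, gi, k))
            )
            sid = f"{'pat' if patient else 'con'}{k:03d}"
            w = _simulate_matrix(cfg, rng, patient)
            matrices[sid] = ConnectivityMatrix(sid, w, node_ids)
            age = float(rng.normal(*COVARIATE_LAWS["age"]))
            edu = float(np.clip(rng.normal(*COVARIATE_LAWS["education"]), 1, 25))
            ftnd = float(np.clip(rng.normal(*COVARIATE_LAWS["ftnd"]), 0, 10))
            if patient:
                scores = {
                    name: float(np.clip(rng.normal(m, sd), 0, None))
                    for name, (m, sd) in CLINICAL_LAWS.items()
                }
                cc = cfg.clinical_coupling
                if cc is not None and cc.coefficient != 0.0:
                    base = (
                        CLINICAL_LAWS[cc.score][0]
                        if cc.intercept is None
                        else cc.intercept
                    )
                    scores[cc.score] = float(
                        base
                        + cc.coefficient * _subject_metric(w, cc.metric)
                        + rng.normal(0.0, cc.noise_sd)
                    )
                rec = SubjectRecord(
                    subject_id=sid,
                    group="patient",
                    age=age,
                    education=edu,
                    ftnd=ftnd,
                    bprs_total=scores["bprs_total"],
                    bprs_factors={
                        k2: v
                        for k2, v in scores.items()
                        if k2 not in ("bprs_total", "hama")
                    },
                    hama=scores["hama"],
                )
            else:
                rec = SubjectRecord(
                    subject_id=sid,
                    group="control",
                    age=age,
                    education=edu,
                    ftnd=ftnd,
                )
            records.append(rec)
    cohort = Cohort(records, matrices, atlas)
    _warn_if_fragmenting(cohort)
    return cohort


def _warn_if_fragmenting(cohort: Cohort) -> None:
    """Warn when the densest threshold likely fragments the networks."""
    sid = cohort.subject_ids[0]
    g = threshold_graph(cohort.matrices[sid], ThresholdGrid().stop)
    comps = list(nx.connected_components(g.graph))
    if not comps or max(len(c) for c in comps) < 0.9 * g.n_nodes:
        logger.warning(
            "largest component covers < 90% of nodes at the top of the "
            "default threshold grid; sigma may be undefined downstream"
        )


def inject_edge_component(
    cohort: Cohort,
    edges: Sequence[tuple[int, int]],
    delta: float,
    group: str = "patient",
) -> Cohort:
    """Shift the weights of ``edges`` by ``delta`` in one group's matrices.

    Creates a known connected component whose mean weight differs between
    groups by ``delta`` (weights clipped into [0, 1]); ground truth for
    NBS power checks.
    """
    if not edges:
        raise ValidationError("empty edge list")
    n = cohort.matrices[cohort.subject_ids[0]].n_nodes
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValidationError(f"edge ({i}, {j}) out of node range")
    new_matrices = {}
    for r in cohort.records:
        m = cohort.matrices[r.subject_id]
        if r.group == group and delta != 0.0:
            w = m.weights.copy()
            for i, j in edges:
                w[i, j] = w[j, i] = np.clip(w[i, j] + delta, 0.0, 1.0)
            m = ConnectivityMatrix(m.subject_id, w, list(m.node_ids))
        new_matrices[r.subject_id] = m
    return Cohort(list(cohort.records), new_matrices, cohort.atlas)
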