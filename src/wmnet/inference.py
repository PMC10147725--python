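"""Permutation-based group comparison and clinical correlations.

Group contrasts use a general linear model with the group indicator plus
nuisance covariates (age, education, nicotine dependence), tested by
Freedman–Lane residual permutation: the reduced (covariates-only) model is
fitted, its residuals are permuted, and the group t-statistic is recomputed
on each reconstructed response. Two-sided p-values use the +1 smoothed
estimator p = (1 + #{|t*| >= |t|}) / (1 + n_perm), so p can never be 0 and
never falls below its floor 1/(n_perm + 1).

No multiplicity correction is applied across features: each is flagged at
the nominal alpha, mirroring the screening convention whose selected set
feeds the classifier. This is a deliberate, documented caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .io import Cohort, ValidationError


@dataclass
class ComparisonResult:
    """One feature's group contrast."""

    feature: str
    coef: float  # group coefficient (patient minus control), covariate-adjusted
    t_obs: float
    p: float  # two-sided permutation p
    direction: str  # "control>patient" or "patient>control"
    cohen_d: float  # unadjusted control-minus-patient standardized difference
    effect_label: str
    n_perm: int


@dataclass
class PartialCorrelationResult:
    feature: str
    clinical: str
    r: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)


def _design(group: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Full design [g, 1, Z] and reduced design [1, Z]; g is patient=1."""
    g = np.asarray(group)
    if g.dtype.kind in "US":
        g = (g == "patient").astype(float)
    g = g.astype(float)
    n = len(g)
    ones = np.ones((n, 1))
    if covariates is None or covariates.size == 0:
        z = ones
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        z = np.hstack([ones, covariates])
    x = np.hstack([g[:, None], z])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    return x, z


def _glm_group_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group-coefficient estimates and t-statistics; y may be (n,) or (n, B)."""
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)  # (p, B)
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 1e-300))
    t = beta[0] / se
    if squeeze:
        return beta[0][0], t[0]
    return beta[0], t


def permutation_glm(
    feature: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Freedman–Lane permutation test of the group effect on one feature."""
    y = np.asarray(feature, dtype=float)
    if len(y) < 6:
        raise ValidationError("need at least 6 subjects")
    if np.ptp(y) == 0:
        raise ValidationError("constant feature")
    x, z = _design(group, covariates)
    coef, t_obs = _glm_group_t(x, y)
    # reduced model: covariates only
    gamma, *_ = np.linalg.lstsq(z, y, rcond=None)
    fitted = z @ gamma
    resid = y - fitted
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(y)) for _ in range(n_perm)]).T
    y_star = fitted[:, None] + resid[perms]  # (n, n_perm)
    _, t_perm = _glm_group_t(x, y_star)
    # relative tolerance so exact permutation ties are counted despite
    # floating-point noise in the recomputed statistic
    thresh = abs(t_obs) * (1.0 - 1e-10)
    p = (1.0 + np.sum(np.abs(t_perm) >= thresh)) / (1.0 + n_perm)
    return {
        "coef": float(coef),
        "t_obs": float(t_obs),
        "p": float(p),
        "n_perm": n_perm,
        "direction": "patient>control" if coef > 0 else "control>patient",
    }


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with pooled (n-1) standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both samples need at least 2 observations")
    nx, ny = len(x), len(y)
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValidationError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def effect_size_label(d: float) -> str:
    """Conventional bands: 0.2 small, 0.5 medium, 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of covariate-residualized vectors, t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        z = np.hstack([np.ones((n, 1)), c])
        rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
        ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if n <= k + 2:
        raise ValidationError("too few observations for the covariate count")
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    tol_x = 1e-12 * max(1.0, float(np.linalg.norm(x)))
    tol_y = 1e-12 * max(1.0, float(np.linalg.norm(y)))
    if k > 0 and (sx <= tol_x or sy <= tol_y):
        # a vector lying in the covariate span is annihilated: r is 0 by
        # construction, not undefined
        return 0.0, 1.0
    if sx == 0 or sy == 0:
        raise ValidationError("degenerate residuals (zero variance)")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def compare_all(
    table: FeatureTable,
    cohort: Cohort,
    n_perm_global: int = 10000,
    n_perm_nodal: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[ComparisonResult], list[str]]:
    """Permutation GLM on every feature; returns results + significant list.

    Global attributes get ``n_perm_global`` permutations, nodal ones
    ``n_perm_nodal``. Cohen's d is reported on the raw (unadjusted) group
    samples, signed control minus patient.
    """
    group = cohort.groups()
    cov = cohort.covariates()
    is_pat = group == "patient"
    results = []
    significant = []
    for k, col in enumerate(table.data.columns):
        y = table.data[col].to_numpy()
        n_perm = n_perm_global if col in table.global_columns else n_perm_nodal
        if np.ptp(y) == 0:
            # a flat feature (e.g. hubness of a never-hub node) carries no
            # group signal; report it as null rather than failing the run
            results.append(
                ComparisonResult(col, 0.0, 0.0, 1.0, "control>patient", 0.0,
                                 "negligible", n_perm)
            )
            continue
        res = permutation_glm(
            y, group, cov, n_perm=n_perm, seed=(seed * 100003 + k) % 2**31
        )
        d = cohens_d(y[~is_pat], y[is_pat])
        results.append(
            ComparisonResult(
                feature=col,
                coef=res["coef"],
                t_obs=res["t_obs"],
                p=res["p"],
                direction=res["direction"],
                cohen_d=d,
                effect_label=effect_size_label(d),
                n_perm=n_perm,
            )
        )
        if res["p"] < alpha:
            significant.append(col)
    return results, significant


def clinical_correlations(
    table: FeatureTable,
    cohort: Cohort,
    features: list[str],
    clinical_vars: list[str] | None = None,
) -> list[PartialCorrelationResult]:
    """Partial correlations of selected features with patients' clinical scores,
    adjusted for age, education and nicotine dependence."""
    patients = [r for r in cohort.records if r.group == "patient"]
    sids = [r.subject_id for r in patients]
    cov = np.array([[r.age, r.education, r.ftnd] for r in patients])
    rows = []
    clinical_vars = clinical_vars or ["bprs_total", "hama"]
    for feat in features:
        x = table.data.loc[sids, feat].to_numpy()
        for cv in clinical_vars:
            vals = []
            for r in patients:
                if cv == "bprs_total":
                    vals.append(r.bprs_total)
                elif cv == "hama":
                    vals.append(r.hama)
                else:
                    vals.append(r.bprs_factors.get(cv, np.nan))
            y = np.asarray(vals, dtype=float)
            if not np.isfinite(y).all() or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r_val, p = partial_correlation(x, y, cov)
            rows.append(
                PartialCorrelationResult(
                    feature=feat,
                    clinical=cv,
                    r=r_val,
                    p=p,
                    n=len(y),
                    covariates=["age", "education", "ftnd"],
                )
            )
    return rows


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
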