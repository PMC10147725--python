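"""LASSO feature selection + linear SVM with repeated cross-validation.

The classifier chain mirrors a common neuroimaging workflow: features that
survive group-difference screening are pruned by an L1-penalized logistic
model (penalty chosen by minimum cross-validated deviance over a 10x5
scheme), then a linear SVM (C = 1) is evaluated with stratified fivefold
cross-validation repeated 100 times; performance is the mean +/- sd over
all 500 fold-evaluations, on the percent scale. Per fold, features are
min-max scaled on the training split and the training parameters are
applied to the test split.

Because screening and LASSO are fitted on all subjects before
cross-validation, the headline accuracy carries selection (leakage) bias;
``leakage_audit`` quantifies it by re-running the chain with selection
nested inside each training fold. Both orderings are exposed and every
report names the one used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ClassifierReport:
    """Cross-validated performance, percent scale, mean +/- sd over folds."""

    accuracy: float
    accuracy_sd: float
    sensitivity: float  # patient-class recall
    sensitivity_sd: float
    specificity: float  # control-class recall
    specificity_sd: float
    kappa: float
    kappa_sd: float
    selected_features: list[str]
    feature_weights: dict[str, float]  # mean |primal weight| over folds
    c_value: float = 1.0
    folds: int = 5
    repeats: int = 100
    n_fold_evaluations: int = 0
    selection_mode: str = "pre-cv"  # "pre-cv" (leaky, faithful) or "nested"
    perm_p: float | None = None
    perm_p_smoothed: float | None = None
    n_perm: int | None = None
    seed: int | None = None


@dataclass
class LeakageAuditReport:
    """Accuracies of the pre-CV (leaky) vs nested selection orderings."""

    accuracy_pre_cv: float
    accuracy_nested: float
    n_features_pre_cv: int
    headline_variant: str = "pre-cv"

    @property
    def optimism(self) -> float:
        return self.accuracy_pre_cv - self.accuracy_nested


def _encode(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        return (labels == "patient").astype(int)
    return labels.astype(int)


def scale_minmax(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map train columns to [0, 1]; apply train's min/range to test.

    Constant train columns are dropped (with a warning); the returned
    boolean mask marks the kept columns. Test values outside the train
    range are NOT clipped.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    lo = train.min(axis=0)
    rng = train.max(axis=0) - lo
    keep = rng > 0
    if not keep.all():
        logger.warning("dropping %d constant columns", (~keep).sum())
    train_s = (train[:, keep] - lo[keep]) / rng[keep]
    test_s = (test[:, keep] - lo[keep]) / rng[keep]
    return train_s, test_s, keep


def kappa_from_confusion(confusion: np.ndarray) -> float:
    """Cohen's kappa with marginal-product chance agreement (2x2 counts)."""
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    if n <= 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        raise ValidationError("chance agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def lasso_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    cs: np.ndarray | None = None,
) -> list[str]:
    """Features with nonzero coefficients on the CV-optimal L1 logistic path.

    The penalty is chosen by minimum mean cross-validated deviance over
    ``repeats`` x ``folds`` stratified splits; columns are standardized
    internally (the selection, not the scale, is what propagates).
    """
    if features.shape[1] < 2:
        raise ValidationError("LASSO selection needs at least 2 features")
    y = _encode(labels)
    x = features.to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x - mu) / sd
    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed % 2**31
    )
    model = LogisticRegressionCV(
        Cs=cs if cs is not None else np.logspace(-2.5, 2.0, 25),
        cv=cv,
        l1_ratios=(1.0,),
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        random_state=seed % 2**31,
        use_legacy_attributes=False,
    )
    model.fit(xs, y)
    coef = model.coef_.ravel()
    selected = [c for c, w in zip(features.columns, coef) if w != 0.0]
    if not selected:
        raise ValidationError(
            "LASSO kept no features at the CV-optimal penalty; consider a "
            "weaker penalty rule or a larger C grid"
        )
    return selected


def _fold_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, float]:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    kappa = kappa_from_confusion(np.array([[tn, fp], [fn, tp]]))
    return acc, sens, spec, kappa


def svm_crossval(
    features: pd.DataFrame,
    labels: np.ndarray,
    c: float = 1.0,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    selection_mode: str = "pre-cv",
) -> ClassifierReport:
    """Repeated stratified fivefold CV of a linear SVM; per-fold scaling."""
    y = _encode(labels)
    x = features.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    accs, senss, specs, kappas = [], [], [], []
    weights = np.zeros(x.shape[1])
    n_folds_done = 0
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed + rep) % 2**31
        )
        for train_idx, test_idx in skf.split(x, y):
            if len(np.unique(y[train_idx])) < 2:
                raise ValidationError("degenerate fold: one class in training")
            xtr, xte, keep = scale_minmax(x[train_idx], x[test_idx])
            clf = SVC(kernel="linear", C=c)
            clf.fit(xtr, y[train_idx])
            pred = clf.predict(xte)
            a, s, sp, k = _fold_metrics(y[test_idx], pred)
            accs.append(a)
            senss.append(s)
            specs.append(sp)
            kappas.append(k)
            weights[keep] += np.abs(clf.coef_.ravel())
            n_folds_done += 1
    weights /= n_folds_done

    def pct(v):
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        return float(100 * v.mean()), float(100 * v.std(ddof=1))

    acc_m, acc_sd = pct(accs)
    sen_m, sen_sd = pct(senss)
    spe_m, spe_sd = pct(specs)
    kap_m, kap_sd = pct(kappas)
    return ClassifierReport(
        accuracy=acc_m,
        accuracy_sd=acc_sd,
        sensitivity=sen_m,
        sensitivity_sd=sen_sd,
        specificity=spe_m,
        specificity_sd=spe_sd,
        kappa=kap_m,
        kappa_sd=kap_sd,
        selected_features=list(features.columns),
        feature_weights={
            c2: float(w) for c2, w in zip(features.columns, weights)
        },
        c_value=c,
        folds=folds,
        repeats=repeats,
        n_fold_evaluations=n_folds_done,
        selection_mode=selection_mode,
        seed=seed,
    )


def _single_cv_accuracy(
    x: np.ndarray, y: np.ndarray, c: float, folds: int, rs: int
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
    accs = []
    for train_idx, test_idx in skf.split(x, y):
        xtr, xte, _ = scale_minmax(x[train_idx], x[test_idx])
        clf = SVC(kernel="linear", C=c)
        clf.fit(xtr, y[train_idx])
        accs.append(np.mean(clf.predict(xte) == y[test_idx]))
    return float(np.mean(accs))


def permutation_test_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    c: float = 1.0,
    folds: int = 5,
) -> dict:
    """One-tailed label-permutation test of the cross-validated accuracy.

    Each permuted run uses one fivefold CV; ``perm_p`` is the plain
    fraction #{perm accuracy >= true accuracy}/n_perm, with a
    +1/(n_perm+1) smoothed companion that can never reach 0.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be positive")
    y = _encode(labels)
    x = features.to_numpy(dtype=float)
    true_acc = _single_cv_accuracy(x, y, c, folds, seed % 2**31)
    rng = np.random.default_rng(seed)
    count = 0
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        acc_b = _single_cv_accuracy(
            x, y_perm, c, folds, int(rng.integers(2**31 - 1))
        )
        if acc_b >= true_acc:
            count += 1
    return {
        "perm_p": count / n_perm,
        "perm_p_smoothed": (count + 1) / (n_perm + 1),
        "true_accuracy": true_acc,
        "n_perm": n_perm,
    }


def _screen(
    x: pd.DataFrame,
    labels: np.ndarray,
    covariates: np.ndarray | None,
    alpha: float,
    n_perm: int,
    seed: int,
) -> list[str]:
    """Group-difference screening (permutation GLM p < alpha)."""
    from .inference import permutation_glm

    selected = []
    for k, col in enumerate(x.columns):
        v = x[col].to_numpy()
        if np.ptp(v) == 0:
            continue
        res = permutation_glm(
            v, labels, covariates, n_perm=n_perm,
            seed=(seed * 7919 + k) % 2**31,
        )
        if res["p"] < alpha:
            selected.append(col)
    return selected


def leakage_audit(
    features: pd.DataFrame,
    labels: np.ndarray,
    covariates: np.ndarray | None = None,
    screen_alpha: float = 0.05,
    n_perm_screen: int = 199,
    lasso_repeats: int = 2,
    folds: int = 5,
    cv_repeats: int = 5,
    c: float = 1.0,
    seed: int = 0,
) -> LeakageAuditReport:
    """Quantify selection bias: pre-CV vs nested screening + LASSO.

    Variant (a), the reproduction default, screens and LASSO-selects on all
    subjects before cross-validation; variant (b) repeats both steps inside
    each training fold. When a selection step keeps nothing, the previous
    feature set is carried forward, so both variants always yield a defined
    accuracy.
    """
    y = _encode(labels)

    def select(x: pd.DataFrame, lab: np.ndarray, cov, s: int) -> pd.DataFrame:
        cols = _screen(x, lab, cov, screen_alpha, n_perm_screen, s)
        sub = x[cols] if cols else x
        if sub.shape[1] >= 2:
            try:
                kept = lasso_select(
                    sub, lab, repeats=lasso_repeats, folds=folds, seed=s
                )
                sub = sub[kept]
            except ValidationError:
                pass
        return sub

    # variant (a): selection on all subjects, then repeated CV
    sel_a = select(features, labels, covariates, seed)
    rep_a = svm_crossval(
        sel_a, labels, c=c, folds=folds, repeats=cv_repeats, seed=seed,
        selection_mode="pre-cv",
    )

    # variant (b): selection nested in each training fold
    x = features
    accs_b = []
    for rep in range(cv_repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed + rep) % 2**31
        )
        for train_idx, test_idx in skf.split(x, y):
            lab_tr = np.asarray(labels)[train_idx]
            cov_tr = None if covariates is None else covariates[train_idx]
            sub_tr = select(
                x.iloc[train_idx], lab_tr, cov_tr, seed + 31 * rep
            )
            xtr, xte, _ = scale_minmax(
                sub_tr.to_numpy(dtype=float),
                x.iloc[test_idx][sub_tr.columns].to_numpy(dtype=float),
            )
            clf = SVC(kernel="linear", C=c)
            clf.fit(xtr, y[train_idx])
            accs_b.append(np.mean(clf.predict(xte) == y[test_idx]))
    return LeakageAuditReport(
        accuracy_pre_cv=rep_a.accuracy,
        accuracy_nested=float(100 * np.mean(accs_b)),
        n_features_pre_cv=sel_a.shape[1],
        headline_variant="pre-cv",
    )
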