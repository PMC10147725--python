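"""End-to-end orchestration: simulate → metrics → compare → NBS → classify.

A :class:`RunConfig` captures every knob of one reproducible run; it
round-trips losslessly through YAML. ``run_all`` executes every stage,
writes every intermediate artifact under the output directory, and emits a
manifest tying outputs to input digests and seeds.

Two named profiles exist: ``full`` uses the complete permutation counts
(10000 global / 5000 nodal / 5000 NBS / 5000 classifier, 100 CV repeats,
46 subjects per group) and ``quick`` a scaled-down set for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, features, inference, io, nbs, simulate
from .graphs import ThresholdGrid
from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "wmnet_run"
    cohort_dir: str | None = None  # load instead of simulating when set
    seed: int = 0
    # synthetic-cohort parameters (used when cohort_dir is None)
    n_per_group: int = 46
    n_nodes: int = 90
    n_modules: int = 6
    effect_modularity: float = 0.0
    effect_sigma: float = 0.0
    effect_nodes: list[tuple[int, float]] = field(default_factory=list)
    # threshold grid
    grid_start: float = 0.001
    grid_stop: float = 0.01
    grid_step: float = 0.001
    # metric / inference counts
    n_null: int = 100
    n_perm_global: int = 10000
    n_perm_nodal: int = 5000
    n_perm_nbs: int = 5000
    n_perm_classifier: int = 5000
    alpha: float = 0.05
    alpha_nbs_primary: float = 0.05
    # classifier
    c_value: float = 1.0
    folds: int = 5
    cv_repeats: int = 100
    lasso_repeats: int = 10
    leakage_mode: str = "pre-cv"  # or "nested" (audit always emitted)
    run_leakage_audit: bool = True

    def __post_init__(self) -> None:
        for name in (
            "n_null",
            "n_perm_global",
            "n_perm_nodal",
            "n_perm_nbs",
            "n_perm_classifier",
            "folds",
            "cv_repeats",
            "lasso_repeats",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @property
    def grid(self) -> ThresholdGrid:
        return ThresholdGrid(self.grid_start, self.grid_stop, self.grid_step)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["effect_nodes"] = [list(t) for t in doc["effect_nodes"]]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["effect_nodes"] = [tuple(t) for t in doc.get("effect_nodes", [])]
        return cls(**doc)


def quick_profile(**overrides) -> RunConfig:
    """Scaled-down defaults for desk-scale runs (minutes, one CPU)."""
    base = dict(
        n_per_group=20,
        n_nodes=32,
        n_modules=4,
        n_null=25,
        n_perm_global=499,
        n_perm_nodal=199,
        n_perm_nbs=199,
        n_perm_classifier=199,
        cv_repeats=10,
        lasso_repeats=2,
        grid_start=0.002,
        grid_stop=0.008,
        grid_step=0.002,
    )
    base.update(overrides)
    return RunConfig(**base)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the end-to-end report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}

    def stage(name):
        logger.info("stage: %s", name)

    # --- cohort -----------------------------------------------------------
    stage("simulate")
    try:
        if config.cohort_dir is not None:
            cohort = io.read_cohort(config.cohort_dir)
        else:
            cohort = simulate.generate_cohort(
                simulate.SimulationConfig(
                    n_per_group=config.n_per_group,
                    n_nodes=config.n_nodes,
                    n_modules=config.n_modules,
                    effect_modularity=config.effect_modularity,
                    effect_sigma=config.effect_sigma,
                    effect_nodes=list(config.effect_nodes),
                    seed=config.seed,
                )
            )
            io.write_cohort(cohort, out / "cohort")
    except ValidationError as exc:
        raise ValidationError(f"stage simulate: {exc}") from exc
    manifest["stages"]["cohort"] = {"n_subjects": len(cohort.records)}

    # --- feature table ----------------------------------------------------
    stage("metrics")
    try:
        table = features.build_feature_table(
            cohort, config.grid, seed=config.seed, n_null=config.n_null
        )
    except ValidationError as exc:
        raise ValidationError(f"stage metrics: {exc}") from exc
    table.write(out / "features.tsv")
    manifest["stages"]["metrics"] = {"n_features": table.data.shape[1]}

    # --- group inference --------------------------------------------------
    stage("compare")
    results, significant = inference.compare_all(
        table,
        cohort,
        n_perm_global=config.n_perm_global,
        n_perm_nodal=config.n_perm_nodal,
        seed=config.seed,
        alpha=config.alpha,
    )
    inference.results_to_frame(results).to_csv(
        out / "comparisons.tsv", sep="\t", index=False
    )
    corr = inference.clinical_correlations(table, cohort, significant)
    io.write_report(corr, out / "clinical_correlations.json", seed=config.seed)
    manifest["stages"]["compare"] = {
        "n_significant": len(significant),
        "significant": significant,
    }

    # --- NBS --------------------------------------------------------------
    stage("nbs")
    nbs_results = nbs.nbs_both_tails(
        cohort,
        cohort.covariates(),
        alpha_primary=config.alpha_nbs_primary,
        n_perm=config.n_perm_nbs,
        seed=config.seed,
    )
    for tail, res in nbs_results.items():
        io.write_report(
            res,
            out / f"nbs_{tail.replace('>', '_gt_')}.json",
            seed=config.seed,
        )
    manifest["stages"]["nbs"] = {
        tail: {"min_fwe_p": res.min_fwe_p, "n_components": len(res.components)}
        for tail, res in nbs_results.items()
    }

    # --- classification ---------------------------------------------------
    stage("classify")
    labels = cohort.groups()
    cov = cohort.covariates()
    if not significant:
        logger.warning("no significant features; classifying on all features")
        screened = table.data
    else:
        screened = table.data[significant]
    if screened.shape[1] >= 2:
        try:
            selected = classify.lasso_select(
                screened,
                labels,
                repeats=config.lasso_repeats,
                folds=config.folds,
                seed=config.seed,
            )
            screened = screened[selected]
        except ValidationError:
            logger.warning("LASSO kept nothing; using screened features")
    report = classify.svm_crossval(
        screened,
        labels,
        c=config.c_value,
        folds=config.folds,
        repeats=config.cv_repeats,
        seed=config.seed,
        selection_mode=config.leakage_mode,
    )
    perm = classify.permutation_test_classifier(
        screened,
        labels,
        n_perm=config.n_perm_classifier,
        seed=config.seed,
        c=config.c_value,
        folds=config.folds,
    )
    report.perm_p = perm["perm_p"]
    report.perm_p_smoothed = perm["perm_p_smoothed"]
    report.n_perm = perm["n_perm"]
    io.write_report(report, out / "classifier.json", seed=config.seed)
    weights_tsv = out / "feature_weights.tsv"
    with open(weights_tsv, "w") as fh:
        fh.write("feature\tweight\n")
        for name, w in sorted(
            report.feature_weights.items(), key=lambda kv: -kv[1]
        ):
            fh.write(f"{name}\t{w:.6g}\n")
    manifest["stages"]["classify"] = {
        "accuracy": report.accuracy,
        "kappa": report.kappa,
        "perm_p": report.perm_p,
        "n_selected": len(report.selected_features),
    }

    # --- leakage audit ----------------------------------------------------
    if config.run_leakage_audit:
        stage("leakage-audit")
        audit = classify.leakage_audit(
            table.data,
            labels,
            cov,
            folds=config.folds,
            seed=config.seed,
        )
        io.write_report(audit, out / "leakage_audit.json", seed=config.seed)
        manifest["stages"]["leakage_audit"] = {
            "accuracy_pre_cv": audit.accuracy_pre_cv,
            "accuracy_nested": audit.accuracy_nested,
        }

    for artifact in sorted(out.glob("*")):
        if artifact.is_file():
            manifest["inputs"][artifact.name] = _digest(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
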