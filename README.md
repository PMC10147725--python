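# wmnet

Weighted white-matter connectome analysis: from per-subject
connection-probability matrices to graph topology, permutation-based group
inference, and SVM classification.

## The problem

Diffusion-MRI probabilistic tractography yields, for each subject, a
symmetric nonnegative matrix `W` whose entry `w_ij` is the connection
probability between brain parcels `i` and `j`. Case-control studies of
such weighted structural networks ask three questions:

1. **Topology.** Do global attributes — weighted clustering coefficient
   `C_p`, characteristic path length `L_p` (edge length `1/w`), modularity
   `Q`, small-worldness `σ = (C_p/C_rand)/(L_p/L_rand)` against
   degree-preserving rewired nulls — or regional attributes (nodal
   efficiency `E_nod(i) = (N−1)⁻¹ Σ_j 1/d_ij`, a 0–4 composite hubness
   score) differ between groups? To avoid single-threshold arbitrariness,
   each attribute is computed over a grid of edge-weight thresholds
   (0.001–0.01, step 0.001) and integrated into an area-under-curve (AUC)
   feature; groups are compared with a covariate-adjusted general linear
   model whose p-values come from Freedman–Lane residual permutation.
2. **Connections.** Do specific edges differ? The network-based statistic
   (NBS) thresholds edge-wise GLM t-tests at a primary alpha, extracts
   connected components of surviving edges, and refers each component's
   size (number of links) to the permutation null of the maximum component
   size, controlling family-wise error.
3. **Diagnosis.** Can the topological features classify subjects? Features
   surviving the group screen are pruned by L1-penalized logistic
   regression (penalty chosen by 10×5-fold CV deviance), and a linear SVM
   (C = 1) is evaluated with 100 repeats of stratified fivefold CV
   (per-fold min-max scaling), reporting accuracy, sensitivity,
   specificity, and Cohen's kappa with a label-permutation significance
   test.

`wmnet` implements this pipeline as a tested Python library. Because
clinical connectome datasets are rarely shareable, it ships a synthetic
cohort generator producing modular weighted networks with injectable group
contrasts (reduced modularity, reduced small-worldness, boosted nodal
efficiency, plantable NBS edge components, clinically coupled scores), so
every stage is testable end to end.

## Worked example

```python
from wmnet import (SimulationConfig, ThresholdGrid, generate_cohort,
                   build_feature_table, compare_all, lasso_select,
                   svm_crossval)

cohort = generate_cohort(SimulationConfig(
    n_per_group=20, n_nodes=24, n_modules=3,
    effect_modularity=0.5, effect_sigma=0.25,
    effect_nodes=[(4, 1.8), (9, 1.8)], seed=1))
table = build_feature_table(cohort, ThresholdGrid(0.002, 0.008, 0.002),
                            seed=1, n_null=10)
results, significant = compare_all(table, cohort,
                                   n_perm_global=499, n_perm_nodal=199, seed=1)
labels = cohort.groups()
selected = lasso_select(table.data[significant], labels, repeats=3, seed=1)
report = svm_crossval(table.data[selected], labels, repeats=20, seed=1)
print(f"{len(significant)} screened, {len(selected)} selected, "
      f"accuracy {report.accuracy:.1f}% +/- {report.accuracy_sd:.1f}%")
```

On this synthetic cohort the run prints

```
26 screened, 7 selected, accuracy 100.0% +/- 0.0%
```

meaning: 26 of the 52 AUC features (4 global + 2×24 nodal) show a group
difference at p < 0.05; the L1 path keeps 7 of them; the linear SVM then
separates the groups almost perfectly — unsurprising, since the injected
effects are large and, as in the workflow reproduced here, feature
selection precedes cross-validation. `wmnet.leakage_audit` quantifies that
selection bias by re-running the chain with selection nested inside each
training fold (`examples/05_classifier.py` shows both numbers).

The `examples/` directory holds one short script per capability
(simulation, metrics, group comparison, NBS, classification); each prints
the numbers it computes and a line on what they mean. A thin CLI mirrors
the pipeline stages: `wmnet simulate`, `metrics`, `compare`, `nbs`,
`classify`, `run-all`, `leakage-audit`.

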