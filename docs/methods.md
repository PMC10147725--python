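# Methods

This note documents the models, conventions and numerical choices behind
`wmnet`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A subject is a symmetric nonnegative `N×N` connection-probability matrix
with zero diagonal (`ConnectivityMatrix`), plus a metadata record (group,
age, education, FTND nicotine score; for patients also BPRS total, its
five factor scores, and HAMA). Matrices are dense CSV (comma separator,
'.' decimal, optional single header row of node ids; row order defines
node order); subject and atlas tables are TSV. Asymmetries up to 1e-9 are
averaged away; anything larger is rejected with the offending cell —
strongly asymmetric tractography outputs must be direction-averaged by the
user first. Node indexing is 0-based internally; all reports carry node
labels, never indices. Result objects serialize to schema-versioned JSON
with the seed and full-precision numbers, and write→read is the identity.

## Graph construction

Thresholds are absolute weight cutoffs on the probability scale: edge
`(i,j)` survives at `τ` iff `w_ij ≥ τ` (ties kept; stated explicitly
because conventions differ). Weights are retained after thresholding —
the analysis is weighted throughout. The consensus grid default is
0.001–0.01 in steps of 0.001 (10 points); edge sets are nested across the
grid by construction. Density-based thresholding is deliberately out of
scope: the grid values live on the weight scale.

## Topological attributes

* **Clustering** — Onnela geometric-mean triangle form,
  `C_i = (k_i(k_i−1))⁻¹ Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3}` with `ŵ = w/max(w)`;
  the standard weighted clustering in brain-network toolkits. Isolated and
  degree-1 nodes get 0; `C_p` is the mean over all nodes.
* **Distances** — edge length `1/w` (the dominant convention for
  probability-weighted connectomes; `−log w` was rejected for
  comparability with the small-world literature). `L_p` is the mean over
  connected ordered pairs; the count of excluded (disconnected) pairs is
  reported alongside. Disconnected pairs contribute 0 to nodal efficiency
  `E_nod(i) = (N−1)⁻¹ Σ_{j≠i} 1/d_ij`. Both conventions keep the metrics
  finite at sparse thresholds.
* **Modularity** — Newman weighted `Q`, maximized by Louvain with 20
  seeded restarts (best `Q` kept, ties by first found).
* **Small-worldness** — `σ = (C_p/C_rand)/(L_p/L_rand)` where the null
  ensemble is Maslov–Sneppen degree-preserving rewiring (10·|E| swap
  attempts per null) with the weight multiset permuted onto the rewired
  topology; `n_null` defaults to 100. σ requires the largest connected
  component to cover ≥ 90% of nodes. The classical σ is sensitive but
  unspecific — near-random graphs with minor clustering can exceed 1 — so
  a cluster-correction flag additionally requires `C_p` to exceed the null
  ensemble's 95th percentile (a one-sided empirical test at α = 0.05).
  This operationalization is a documented convention of this package, not
  a reconstruction of any particular toolbox's procedure.
* **Hubness** — integer 0–4: +1 each for strength in the top 20%,
  weighted betweenness (1/w edge lengths) in the top 20%, clustering in
  the bottom 20%, and `E_nod` in the top 20%. Ties at a percentile cutoff
  are included; when a cutoff degenerates onto the distribution's opposite
  extreme (e.g. a star's leaves all share the minimum strength), inclusion
  becomes strict so the criterion stays discriminative, and when all
  values are identical every node qualifies (so fully symmetric graphs
  score uniformly). The 20% cutoffs are frozen conventions.

## Threshold integration

Each attribute's curve over the grid is collapsed by the trapezoidal rule
into one AUC value per subject. The feature table has `4 + 2N` columns:
σ, `C_p`, `L_p`, `Q` plus `E_nod` and hubness per node. Integer hubness
curves get the same AUC treatment as continuous metrics (the aggregation
is not otherwise pinned down; uniformity was chosen). A σ curve undefined
at some threshold (fragmented graph) fails loudly with the subject id
rather than imputing; the synthetic generator's defaults avoid that
regime. Per-subject metric seeds are derived from the master seed and a
CRC of the subject id, so the table is independent of file or row order.

## Group inference

Each feature is tested with a GLM containing the group indicator
(patient = 1) and nuisance covariates (age, education, FTND). P-values
come from Freedman–Lane permutation — fit the covariates-only model,
permute its residuals, refit — which is the recommended scheme when
nuisance covariates are present; raw label permutation would not respect
them. The estimator is the +1-smoothed two-sided
`p = (1 + #{|t*| ≥ |t|})/(1 + B)`, which never reaches 0 and respects the
floor `1/(B+1)`; exact permutation ties are counted using a 1e-10
relative tolerance on `|t|`. Defaults: 10 000 permutations for the four
global features, 5 000 for nodal ones, flagging at p < 0.05 with the
contrast direction reported. **No multiplicity correction is applied**
across the `2N + 4` features: the flagged set is a screening set feeding
the classifier, and the uncorrected convention is kept deliberately — a
prominent caveat, not an oversight. Cohen's d is reported on the raw
group samples (pooled n−1 SD, signed control minus patient) with the
0.2/0.5/0.8 small/medium/large bands. Partial correlations between
selected features and patients' clinical scores residualize both vectors
on the covariates and use the t distribution with `n − k − 2` df; a
vector lying in the covariate span is reported as r = 0 rather than
undefined.

## Network-based statistic

Edges are testable when present (nonzero) in at least 50% of subjects of
each group — a masking convention to avoid near-empty edges. Edge-wise
group t-statistics use the same Freedman–Lane GLM; a one-tailed primary
threshold (default p < 0.05) defines suprathreshold edges, whose connected
components are measured in links. Each permutation recomputes all edge
t-values from re-permuted reduced-model residuals and records the maximum
component size; a component's FWE p is
`(1 + #{max* ≥ size})/(1 + B)` (default B = 5000). Both tails are run and
reported separately by default since the contrast direction of interest
is not always known a priori.

## Classification

The reproduction-default ordering is: screen features by the group GLM
(p < 0.05), prune by L1-penalized logistic regression — penalty chosen by
minimum mean CV deviance over 10 repeats of stratified fivefold CV
(minimum-deviance, not 1-SE, which would select a much smaller set) with
internal z-scoring — then evaluate a linear SVM (C = 1, no kernel or C
search) with 100 repeats of stratified fivefold CV. Per fold, features are
min-max scaled on the training split and the training parameters applied
to the test split (values may leave [0, 1]; constant training columns are
dropped with a warning). Performance is the mean ± SD over all 500
fold-evaluations of accuracy, sensitivity (patient recall), specificity
(control recall) and Cohen's kappa, on the percent scale, plus mean
absolute primal weights per feature. Folds are stratified (plain random
folds could produce one-class training splits at n = 46 + 46).

Significance uses one-tailed label permutation: each of the 5000
permutations runs a single fivefold CV (not the full 100-repeat scheme,
which the description of the procedure implies and which would be
computationally enormous); `perm_p` is the plain fraction
`#{acc* ≥ acc}/B` with a +1-smoothed companion reported alongside.

**Leakage.** Because screening and LASSO precede cross-validation, the
headline accuracy carries selection bias. `leakage_audit` runs the chain
twice on the same data — selection before CV vs selection nested in each
training fold — and reports both accuracies; every classifier report names
the ordering used (`selection_mode`). When a selection step keeps nothing
(common on null data), the previous feature set is carried forward so both
audit variants stay defined.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: two balanced
groups (default 46 per group; 90-node networks, 6 modules). Control
networks are weighted planted-partition graphs: within-module pairs are
connected with probability 0.85 and carry log-normal weights with median
0.02 (s = 0.3 on the log scale), between-module pairs with probability
0.15 and median 0.008. These defaults were chosen so that control networks
are genuinely small-world (σ ≈ 1.3–2.0 across the grid, cluster check
passing), modular (Q ≈ 0.55), and stay connected over the whole default
threshold grid, while the grid still prunes weak between-module edges
progressively. An earlier, more weight-heterogeneous parameterization made
weighted path length so much longer than its rewired null that σ fell
below 1, which inverted the direction of the rewiring effect; the law was
re-designed, not tuned, to restore the phenomenology the generator must
express.

Patient effects: `effect_modularity` shrinks the within/between log-weight
contrast toward its midpoint (fraction 0–1); `effect_sigma` rewires a
fraction of edges to random absent pairs (destroying triangles and hence
σ); `effect_nodes` multiplies all weights incident to chosen nodes
(raising their `E_nod` and strength); `inject_edge_component` shifts a
chosen edge set by a constant in one group, creating ground truth for NBS
power checks. Clinical scores are drawn from laws matching a dependence
cohort (e.g. BPRS total 42.8 ± 11.0) and can be linearly coupled to a
per-subject network summary with Gaussian noise, matching the assumptions
of the Pearson partial-correlation analysis. Covariates share one law
across groups (matched in expectation). Per-subject random streams derive
from `SeedSequence((seed, group_index, subject_index))`, so enlarging a
cohort never reshuffles existing subjects.

What the generator does **not** model: distance-dependent connection
weights, realistic degree distributions of cortical parcellations,
tractography artifacts (gyral bias, false continuations), or
site/scanner covariance. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under a controllable
model — not that real acquisition noise behaves this way.

## Problem sizes in tests and the acceptance script

Desk-scale runs use scaled-down conditions chosen as this package's test
profile: 16–24-node networks, 10–20 subjects per group, 4–30 rewired
nulls, 49–999 permutations, and 2–20 CV repeats; calibration claims use
150–200 simulated cohorts. The full-size profile (`RunConfig` defaults:
46 per group, 100 nulls, 10 000/5 000/5 000/5 000 permutations, 100 CV
repeats) is exposed via `wmnet run-all --profile full`.

## Known limitations

* The hubness composite and the σ cluster-correction are frozen
  conventions of this package; other toolboxes define them differently.
* The uncorrected feature screen inflates the selected-feature count by
  design; users wanting FWE/FDR control must apply it downstream.
* Louvain is a heuristic: `Q` is a lower bound on the optimum, mitigated
  by restarts.
* The permutation classifier test inherits the discreteness of fold
  accuracies at small n; the smoothed p is conservative near ties.
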