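# prnfs — phenotype-relevant network-based feature selection

Finding reproducible prognostic biomarkers in tumor omics data is hard:
with tens of thousands of features and a few hundred patients, many
unrelated feature subsets fit the training data equally well, and even
signatures selected with the help of genome-scale interaction networks
often do no better than random gene sets.  `prnfs` implements the
alternative strategy of constraining selection to a small
**phenotype-relevant gene-regulatory network** — a curated subnetwork (for
example the epithelial–mesenchymal-transition program in lung
adenocarcinoma) covering a few percent of the feature space — and
integrating it with several omics levels: gene expression (GE), DNA
methylation (DM) and copy-number alteration (CNA).

The package is a complete, tested pipeline for researchers in
computational cancer genomics:

* **Network model** — edge-list I/O, adjacency / degree / normalized
  Laplacian matrices, degree-preserving random-network nulls, and
  variance-based node filtering.
* **Ten feature-selection algorithms** behind one contract
  `(view, outcome, optional network, k) → FeatureSet`: Welch-*t* ranking,
  Lasso, network-constrained Lasso, greedy subnetwork search scored by
  mutual information (addDA2-style) or Cox p-values (Survnet-style),
  personalized PageRank (NetRank), random-walk-kernel-smoothed *t*
  statistics (stSVM-style), univariate Cox, L1-penalized Cox, and
  multiple-subset sampling (MSS).
* **Benchmark harness** — repeated stratified k-fold cross-validation with
  shared folds, SVM / random-forest classification, AUC / AUPR / accuracy /
  odds ratios, comparative baseline groups (random networks, whole feature
  space, hallmark gene lists), threshold sensitivity, and
  frequently-selected-feature (FSF) aggregation.
* **Association-rule mining** — mean-threshold binarization and Apriori
  with prognosis-class consequents, scored by support / confidence / lift.
* **Survival stratification** — single- and multi-omics signature
  combination, k-means / spectral / Ward clustering, Kaplan–Meier curves
  and k-group log-rank tests.
* **Synthetic-data generator** — scale-free regulatory networks, planted
  connected prognostic modules split across omics levels, and
  proportional-hazards survival with calibrated censoring, so every stage
  is testable without access to patient data.

## The statistics at the core

**Network-constrained Lasso** minimizes, for weights *w*, labels *Y* and
graph *G* with adjacency *A*,

    (1/2n)‖Y − Xw‖² + α [ λ‖w‖₁ + (1−λ) Σ_{i<j} A_ij (w_i − w_j)² ]

so adjacent genes are pushed toward similar weights (the quadratic term is
the graph-Laplacian form).

**NetRank** iterates a damped, personalized PageRank over the network,

    r_j ← (1−d)·s_j + d · Σ_i A_ij r_i / deg_i ,

with outcome-driven personalization s (per-node |t| or |Cox z|).

**Random-walk-kernel smoothing** (stSVM) multiplies gene-wise *t*
statistics by the *p*-step random-walk kernel

    K = ((α−1)·I + D^{−1/2} A D^{−1/2})^p ,  α ≥ 2,

and ranks features by the smoothed statistic  t̃ = tᵀK.

**Association rules** X ⇒ Y are filtered by
support(X∪Y) = |{t: X∪Y ⊆ t}|/|T|, confidence = supp(X∪Y)/supp(X) and
lift = supp(X∪Y)/(supp(X)·supp(Y)).

## Worked example

```python
from prnfs import simulate_study, GeneratorConfig, generate_grn
from prnfs.selection import select
from prnfs.benchmark import make_cv_plan, run_benchmark, fsf
from prnfs.survival import combine_signatures, stratify

net = generate_grn(74, attachment=2, seed=7)        # 74-node scale-free GRN
cfg = GeneratorConfig(n_samples=200,
                      n_features_per_level={"GE": 500, "DM": 500},
                      effect_size=1.0,
                      level_split={"GE": 1.0, "DM": 1.0}, seed=1)
study = simulate_study(net, cfg, signature_size=20)  # 20-node planted module

y = study.labels.binary()                            # poor=1 / good=0
X = study.dataset.levels["GE"].loc[y.index]
fs = select("stSVM", X, y, net=study.network, k=20)
print(len(set(fs.features) & set(study.signature_nodes)))   # 19

plan = make_cv_plan(study.labels, n_folds=5, n_repeats=3, seed=1)
records, histories = run_benchmark(
    study.dataset, study.labels, study.survival,
    [("emt", study.network)], ["stSVM"], plan, level="GE", k=20, seed=1)
print(round(records["auc"].mean(), 3))               # 0.72

top = fsf(histories[("stSVM", "emt")], 20)           # frequently selected
top.context["level"] = "GE"
sig = combine_signatures([top], study.dataset)
res = stratify(sig, study.survival, method="kmeans", k=3, seed=1)
print(res.statistic, res.df, res.p_value)            # 86.19 2 1.92e-19
```

The run prints: 19 of the 20 planted features are recovered by
network-smoothed *t* ranking; the cross-validated AUC of the selected
20-feature signatures is 0.72 (0.5 would be chance); and clustering the
whole cohort on the FSF signature separates three survival groups with a
log-rank chi-square of 86.2 on 2 degrees of freedom (p ≈ 2·10⁻¹⁹) —
the planted prognostic structure is found end to end.

A command-line interface mirrors the library
(`prnfs simulate|select|run|rules|stratify|summarize`); `prnfs run
--out DIR` executes the full demo pipeline and writes long-format TSV
tables plus a manifest with reproducibility hashes.

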