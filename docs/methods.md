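# Methods

## Problem setting and model

`prnfs` addresses two-group prognosis prediction (good vs poor survival)
from multi-omics tumor profiles, under the working hypothesis that
constraining feature selection to a small phenotype-relevant regulatory
network yields more reproducible signatures than searching the whole
feature space or genome-scale networks.  The pipeline composes five
stages: (1) network representation, (2) feature selection per omics level,
(3) cross-validated classification benchmarking with random-network and
whole-space baselines, (4) association-rule mining on the selected
signatures, and (5) signature-based survival stratification.

Prognosis classes derive from survival thresholds: a patient is *poor* if
an event is observed before `low_days` and *good* if follow-up exceeds
`high_days` regardless of event status (the threshold is already
outlived).  Patients censored before `high_days` have unknowable class and
are excluded from classification — survival analysis still uses them.  The
default thresholds are (700, 1400) days; the alternative printed settings
(single 3-year cut, 900/1200, 500/1500) are available for sensitivity
runs via `THRESHOLD_SETTINGS` and `benchmark.threshold_sensitivity`.

## Network conventions

Networks are undirected; edge weights default to 1 (regulatory edge types
are not distinguished downstream).  With adjacency A and degree D, the
symmetric normalization is S = D^{-1/2} A D^{-1/2} and the normalized
Laplacian L = I − S.  Isolated nodes receive D^{-1/2} entries of 0, so
their rows of S are zero and every kernel and propagation operator remains
well defined on arbitrary subnetworks; under NetRank an isolated node
keeps exactly its personalization share (1−d)·s.  Node symbols are
case-sensitive; one node may map to one feature per omics level through an
optional level map (identity by default).  Random-network nulls preserve
the reference's edge structure exactly and resample node labels uniformly
without replacement from the level's feature pool, destroying biological
content while matching size and degree sequence.

A bundled 74-node fixture (`data/synthetic_core_grn_74.edges`) is a
synthetic scale-free stand-in for a curated core regulatory network; it
carries no biological meaning and exists so examples and tests run without
curation.

## Feature-selection algorithms

All ten selectors share one contract and one ranking convention: scores
sorted non-increasing, ties broken lexicographically by feature id, at
most k features returned (k defaults to 20, matching a signature size of
20 features per training fold).

* **t-test** — Welch two-sample t per feature, rank by |t|.
* **Lasso** — squared loss on ±1 labels along a coordinate-descent path;
  the smallest penalty with ≤ k active features wins; order by |w|.
* **NetLasso** — objective (1/2n)‖y−Xw‖² + α[λ‖w‖₁ + (1−λ)Σ_{i<j}A_ij(w_i−w_j)²].
  The quadratic penalty is folded into augmented least-squares rows
  √(A_ij)(e_i−e_j), so the whole problem is an ordinary Lasso on the
  augmented design; features unmapped to the network automatically receive
  only the L1 term.  The network difference term is squared (the Laplacian
  quadratic form): an unsquared signed sum is unbounded below and cannot
  serve as a penalty.  λ=1 reduces exactly to Lasso; α=0 to unpenalized
  least squares.
* **NetRank** — damped update r ← (1−d)s + d·Pᵀr with P = D^{-1}A, solved
  by power iteration (d = 0.85, tol 1e-9, ≤ 10⁴ iterations).  The bare
  update is outcome-independent, so the personalization s defaults to the
  per-node |t| (labels) or |Cox z| (survival) normalized to mean 1; s ≡ 1
  reproduces the literal damped ranking.
* **stSVM-style ranking** — t̃ = tᵀK with the p-step random-walk kernel
  K = ((α−1)I + S)^p; α ≥ 2 guarantees positive semidefiniteness; defaults
  α=2, p=3.  Unmapped features keep their raw |t|, since the network
  typically covers only part of a level.
* **addDA2-style subnetwork search** — greedy growth from every measured
  node, preferring the neighbor that maximizes the metagene score; the
  metagene is the row-sum ("addition") of member z-scored values,
  binarized at its mean and scored by mutual information (bits) with the
  class labels.  Growth stops at `max_size` (10) or when the relative
  score gain drops below `min_improvement` (0.05).  Member features of the
  top subnetworks are emitted until k are collected.
* **Survnet-style search** — same search scored by −log10 of the Wald p of
  a univariate Cox fit on the metagene.
* **Cox** — univariate Cox proportional-hazards per feature, rank by |z|.
* **RegCox** — L1-penalized Cox along a Coxnet path; smallest penalty with
  ≤ k active features.
* **MSS** — 1000 random subsets of 20 features, each scored by 3-fold
  inner-CV AUC of a linear SVM; a feature's score is the mean AUC of the
  subsets containing it.

The univariate Cox fit is a hand-written one-dimensional Newton
maximization of the Breslow partial likelihood (ties pooled into shared
risk sets), with step halving and a (0,0,1) convention for constant
covariates.  It is written in-package because subnetwork search evaluates
it thousands of times per fold; the search additionally batches all
frontier candidates into one vectorized Newton solve.  Correctness is
checked against lifelines (tie-free data, where Efron and Breslow
coincide) and against direct grid maximization of the Breslow likelihood
(tied data).

## Benchmark harness

Cross-validation is stratified k-fold repeated R times (study-scale
default 10×30), with the same fold plan reused for every algorithm,
network and baseline within a level, so per-fold metrics are pairable.
Selection happens on the training split only; a linear-kernel SVM (or
random forest) is trained on the selected columns; held-out decision
values are sigmoid-mapped so the 0.5 cutoff coincides with the decision
boundary.  Metrics: AUC (Mann–Whitney with half-credit ties), AUPR
(monotone precision-envelope interpolation), accuracy and confusion
counts at 0.5, odds ratio (TP·TN)/(FP·FN) with the Haldane–Anscombe 0.5
correction when any cell is empty.  Single-class test folds cannot arise
under stratification with class counts ≥ folds, but are guarded: the
metric is recorded as missing and excluded from means.  An empty selection
records AUC 0.5 and a flag.  Frequently-selected features (FSFs) are
ranked by how often they appear across all (repeat × fold) selections.

## Synthetic generator

The generator emulates the data structure the analysis assumes, not any
particular cohort: z-scored Gaussian features; a connected planted module
(grown breadth-first from a random start, preferring hubs) whose features
separate a balanced latent binary risk group by a standardized shift
δ·split_level (DM shifts oppose GE, mimicking promoter methylation);
exponential proportional-hazards event times with hazard
λ0·exp(β·risk); and independent exponential censoring whose rate is
calibrated by bisection so the expected censored fraction hits
`censor_rate`.  Defaults: n=200 samples, 500 features/level, δ=1,
level split GE 0.5 / DM 0.35 / CNA 0.15 (GE and DM carry most signal),
λ0 = ln2/2000 per day (median ≈ 2000 days at risk 0), β=1.5, 30%
censoring.  In the *complementary* scenario each module node carries its
full signal on exactly one of GE/DM (round-robin), so no single level sees
the whole signature — the regime where multi-omics combination pays.
Within a level all planted shifts share a sign, which the additive
metagene aggregation can exploit; mixed-sign modules would penalize the
addition operator specifically.

Everything the generator does not model — batch effects, missing values,
feature correlation beyond the module, non-proportional hazards,
platform-specific noise — limits what passing tests prove about real
cohorts: they demonstrate that the pipeline recovers structure it is
designed to find, not that such structure exists in any given dataset.

All randomness flows from one integer master seed through tagged
`SeedSequence` spawn keys (`prnfs._seeds`), so every stage is
bit-reproducible and statistically independent of the others.

## Rule mining

Signature features are binarized at their per-feature mean (values equal
to the mean map to *low* — the tie rule is arbitrary but deterministic);
each labeled sample becomes a transaction of `feature_LEVEL=state` items
plus one `prognosis=good|poor` class item; excluded samples are dropped.
Apriori grows frequent feature itemsets levelwise with anti-monotone
pruning and emits rules with class-item consequents, default floors
support ≥ 0.1 and confidence ≥ 0.8, antecedents of at most 3 items
(matching the arity of typical reported rules).  Output ordering is
(confidence desc, lift desc, support desc, lexicographic), making mining
invariant to transaction order.  The implementation is in-package because
no Apriori implementation ships with the scientific Python stack; it is
verified against exhaustive enumeration.

## Survival stratification

Single-omics signatures are column-concatenated on the shared samples and
z-scored; samples are clustered into k=3 groups (k-means best-of-20
restarts; spectral clustering with RBF affinity and median-heuristic
bandwidth — a standard default where no affinity is prescribed; Ward
hierarchical for the external-cohort protocol).
Kaplan–Meier curves and the k-group log-rank test (hypergeometric
variance at ties) come from lifelines.  P-values are reported unadjusted;
pipeline outputs add a Benjamini–Hochberg column when many
algorithm×combination cells are tested.

## Scale choices and numerical notes

Directional claims (true network > random networks; FSF ≥ per-fold
selection; multi-omics < single-omics log-rank p) are exercised at desk
scale — 5 repeats × 5 folds, 10 random networks, 5–10 generator seeds —
rather than the study-scale 30×10×150, keeping the full suite and the
acceptance script to a few minutes while leaving the compared quantities
paired and the tests one-sided.  Convergence tolerances: NetRank 1e-9
(max-abs change), Lasso/NetLasso coordinate descent 1e-10, univariate Cox
Newton 1e-9 on the step with halving, vectorized search Newton 1e-8 with
step clipping at ±2 (score use only).  The paired network-advantage test
pools per-fold AUC differences across all random-network replicates.

## Known limitations

* The ten selectors follow the published formulas and descriptions, not
  the original implementations' exact protocols (e.g. DA2 discretization
  is mean-threshold binarization; MSS inner protocol is 3-fold AUC).
* Exponential survival and independent censoring are the simplest
  PH-consistent choices; real follow-up is messier.
* Greedy subnetwork scores are optimistically biased by the search
  (multiple testing across seeds/growth steps); scores are used for
  ranking, not inference.
* Integrative clustering methods beyond k-means/spectral/hierarchical
  (e.g. similarity-network fusion, latent-variable joint clustering) are
  out of scope.
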