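# Methods

## Model and procedure space

The unit of evaluation is a *gene-selection procedure*: a deterministic
map from a labelled training matrix to a prediction rule, composed of
gene ranking → direction filtering → top-k selection → optional feature
construction → classifier fitting. The workbench treats every procedure
as a black-box prediction rule and compares them on one number, the
.632+ bootstrap error. The grid crosses

| axis | values | notes |
| --- | --- | --- |
| statistic | ttest, wilcoxon, infogain | see below |
| pattern | total, up, down | direction relative to the positive class |
| k | user grid; default {10, 15, 20, 25, 30, 50, 70, 100, 200} | spans the range typically examined for two-class microarray panels |
| discretize | off, on | MDL interval indices as classifier input |
| feature-vector addition | off, on | up/down patterns only |
| classifier | svm, random_forest | |

yielding 12 + 24 + 24 = 60 procedures per k with all defaults.

## Ranking statistics

* **ttest** — Welch's unequal-variance two-sample t with two-sided p
  (Welch–Satterthwaite df). Genes are ranked by ascending p, ties broken
  by descending |t| and then file order, so output is bit-reproducible.
  Degenerate genes (zero variance in both classes, equal means) are
  defined as t = 0, p = 1; zero variance with unequal means gives p = 0.
* **wilcoxon** — Mann–Whitney U. Exact two-sided p when
  min(n₁, n₂) ≤ 12 and the gene has no ties, otherwise the normal
  approximation with tie and continuity corrections; rank key
  (p ascending, |U − n₁n₂/2| descending, file order). All-tied genes get
  p = 1.
* **infogain** — information gain in bits of the partition produced by
  Fayyad–Irani MDL discretization of that gene (below); genes with no
  accepted cut score 0; rank key (gain descending, file order).

Direction calls: a gene is *up* iff its mean in the positive class
strictly exceeds its mean in the other class; exact ties are called
*down* (arbitrary but documented and stable). The positive class defaults
to the lexicographically smaller label and is recorded in every report.

No multiple-testing correction is applied: ranks, not significance
claims, drive selection, and k caps the list.

## MDL discretization

Recursive binary splitting of the sorted values: each node proposes the
cut minimizing the weighted class entropy of the two halves (candidates
are midpoints between adjacent distinct values; the leftmost minimizer is
taken for determinism) and accepts it only if

    gain > [log2(N−1) + log2(3^k − 2) − (k·H − k₁·H₁ − k₂·H₂)] / N

with N the node size, k/k₁/k₂ the class counts present and H the
entropies in bits. Accepted cuts recurse on both sides; `max_cuts = 1`
gives a single-split mode. Interval encoding is half-open —
(−∞, c₁), [c₁, c₂), …, [c_m, ∞) — identically at fit and apply time, and
values outside the training range fall in the outer intervals. Cuts are
always learned on training samples only. The implementation uses
cumulative class counts (numpy); the test suite checks it cut-for-cut
against an independent naive pure-Python recursion and checks exact
Wilcoxon p-values against full rank-assignment enumeration.

## Feature construction

Discretized inputs are fed to classifiers as small ordinal integers (not
one-hot), preserving interval order. Feature-vector addition sums the raw
expression vectors of the k selected genes into one composite feature
that *replaces* them (an append mode exists behind `fva_mode`); with k
same-direction genes of shared gap δ and independent noise σ the
composite's standardized gap grows like √k — the amplification/outlier-
offset mechanism, verified by Monte Carlo in the tests. No per-gene
standardization precedes the sum, so the composite is scale-sensitive by
design. When both transforms are on, the composite is formed first from
raw values and then discretized; discretizing first would destroy the
amplification.

## Classifiers

SVM: RBF kernel, C = 1, γ = 1/p, with per-feature standardization learned
on training data and stored in the model. Random forest: 500 trees,
√p candidate features per split, fully seeded. Neither is tuned — the
grid compares selection strategies, not hyperparameter search — and every
hyperparameter is overridable (`rf_trees`, `svm_c`, …).

## .632+ bootstrap

B = 100 replicates by default. Replicate r draws n samples with
replacement using a generator seeded by (master_seed, r); draws whose
in-bag set has fewer than two samples of either class are redrawn with
the next derived seed (cap 50). Two per class — slightly stronger than
merely requiring both classes — because the scoring statistics inside the
resampled procedure need per-class variances and ranks; the redraw is
rare at workable class balances and keeps the marginal bootstrap
distribution intact. The *entire* procedure is refitted on each in-bag
set (selection included) and predicts its out-of-bag samples; err⁽¹⁾
averages each sample's own out-of-bag error rate and then averages over
samples, excluding (and counting) samples never out-of-bag. γ uses the
full-data resubstitution model's predicted-class proportions. The blend
follows the formulas in the README, with R defined as 0 unless
err1′ > err̄ and γ > err̄, then clipped to [0, 1], which resolves all
degenerate inputs; consequently ŵ ∈ [0.632, 1] and the estimate is
sandwiched between err̄ and err1′ (property-tested over 10⁴ random
triples).

Seeding: every replicate / procedure / classifier seed derives from the
master seed via `numpy.random.SeedSequence` hashing of
(master seed, canonical procedure index, replicate, role). Grid execution
parallelizes over procedures (joblib/loky); because seeds are derived,
reports are byte-identical for any worker count.

## Synthetic data

The generator emulates a preprocessed two-class expression matrix:
baseline 8.0 (a typical log2-intensity level) plus iid Gaussian noise
(σ = 1), with planted informative genes shifted by ±effect·σ in the
positive class (defaults: 2000 genes, 30 + 30 samples, 20 up + 20 down,
effect 2). Optional outlier samples receive an additive spike
(magnitude 5σ on a random 10% of genes) to exercise the composite's
outlier-offset behaviour. It deliberately omits real-array artifacts —
probe effects, batch structure, correlated gene blocks, heavy tails —
so passing tests demonstrate correctness of the machinery and calibration
under the stated model, not performance on real microarrays.

One calibration subtlety: with 30 + 30 samples the rank-sum statistic is
discrete and all genes share one p-value lattice (atoms ≈ 0.012 near the
center), so a naive KS test of the p-values against the continuous
uniform rejects a perfect null far above its nominal level (~7.5%
measured at α = 0.01). The null-calibration tests therefore apply the KS
test to the exact-null randomized probability integral transform of
|U − n₁n₂/2| (exact U pmf by dynamic programming over ranks), which is
exactly Uniform(0,1) under H₀; since the two-sided p is a strictly
decreasing function of the folded statistic, this is the calibration
statement for the p-values on the lattice they live on.

## Problem sizes in the shipped tests and acceptance script

Grid-level checks run on reduced grids chosen to exercise every code path
while staying desk-scale: the null-calibration run uses the 12-procedure
total-pattern block (2000 genes, 30 + 30 samples, B = 100, forests at 150
trees via the standard override); signal recovery uses the wilcoxon ×
total × {svm, rf} pair at k = 40, B = 50; the parallel-determinism check
uses a 6-procedure grid at B = 10 and workers ∈ {1, 2, 4}. These sizes
are the package's own test-design choices; the library defaults remain
B = 100 and 500 trees.

## Known limitations

* Two classes only; no multi-class extension.
* Input is assumed preprocessed (no normalization, background correction
  or platform-format parsing); values are used as given, log-scaled or not.
* The composite feature is unweighted and scale-sensitive.
* No gene clustering in the selection step and no cross-validation
  estimators; the .632+ bootstrap is the single evaluation currency.
* Model objects are in-memory only; no serialization-format guarantee.
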