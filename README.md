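# genegrid

A gene-selection workbench for two-class expression data. Given a genes ×
samples matrix with a binary phenotype, no single ranking statistic or
classifier is best for every dataset — so instead of picking one,
`genegrid` enumerates a grid of complete *gene-selection procedures*,
estimates each one's generalization error with the .632+ bootstrap, and
reports the procedures with the smallest error using the fewest genes,
together with the genes they select.

A procedure is one choice from each of:

* **ranking statistic** — Welch's two-sample *t* (parametric), the
  Wilcoxon rank-sum / Mann–Whitney *U* (non-parametric), or information
  gain under Fayyad–Irani MDL entropy discretization (model-free);
* **expression pattern** — rank all genes (*total*), or only genes
  up-regulated or down-regulated in the positive class;
* **k** — the number of top-ranked genes to keep;
* **feature discretization** — optionally replace classifier inputs by MDL
  interval indices;
* **feature-vector addition** — optionally sum the *k* selected
  same-direction gene vectors into a single composite feature (only
  defined for up/down patterns), which amplifies a shared pattern and
  averages out single-gene outliers;
* **classifier** — RBF-kernel SVM (C = 1, γ = 1/p, standardized inputs)
  or a 500-tree random forest.

With all options and one k this yields 60 procedures: 12 for the total
pattern and 24 each for up/down.

## The .632+ bootstrap

Each procedure is scored as a single prediction rule. With resubstitution
error err̄, leave-one-out bootstrap error err⁽¹⁾ (each sample predicted
only by replicates in which it was out-of-bag), and no-information rate
γ = Σ_c p_c (1 − q_c):

    err1′ = min(err⁽¹⁾, γ)
    R     = (err1′ − err̄) / (γ − err̄)      (0 unless err1′ > err̄ < γ; clipped to [0, 1])
    ŵ     = 0.632 / (1 − 0.368 R)
    Err.632+ = (1 − ŵ)·err̄ + ŵ·err1′

Gene selection is re-run **inside every bootstrap replicate**; selecting
once on the full data and only refitting the classifier would leak the
held-out labels into the gene list and bias the estimate down. The
package's null-data tests guard exactly this.

## Worked example

```
genegrid simulate --genes 2000 --n1 30 --n2 30 --up 20 --down 20 \
    --effect 2 --seed 7 --out sim/
genegrid run --input sim/matrix.tsv --k 10,20,40 --bootstrap 50 \
    --discretize off --fva off --patterns total --seed 17 --out results/
```

prints (numbers from this exact invocation):

```
dataset: 2000 genes x 60 samples (positive class 'case')
evaluating 18 procedures (B=50, seed=17, workers=1) ...
best .632+ error 0 at k=10 (3 tied procedure(s)):
  ttest/total/k=10/svm
  wilcoxon/total/k=10/svm
  infogain/total/k=10/svm
report written to results
```

i.e. of the 18 evaluated procedures (3 statistics × 2 classifiers × 3
values of k, total pattern, no optional transforms), three SVM-based
procedures tie at a .632+ error of 0 and the ranking rule keeps the
smallest gene count, k = 10: at a 2-SD planted effect the workbench finds
a near-perfect rule and reports every procedure that achieves it.
`results/grid.tsv` holds one row per procedure (errors, status, selected
genes), `best.tsv` the tied winners, `report.json` the full
machine-readable report.

The same workbench runs on real data: a tab-delimited matrix whose first
row is sample ids, optional second row `class <TAB> label…` (or
`--labels FILE`), then one row per gene. The library surface mirrors
scikit-learn — `ProcedureClassifier(statistic="wilcoxon", pattern="down",
k=10, classifier="svm").fit(X, y)` works inside sklearn pipelines and
model selection.

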