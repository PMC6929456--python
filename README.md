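# relabeler

Post hoc correction of cell-type annotations in single-cell RNA-seq data.

Cell types in scRNA-seq experiments are usually assigned by a mix of marker
genes, clustering and human judgement, and a small fraction of cells end up
with the wrong label. `relabeler` takes an expression matrix *X* (N cells ×
M genes) together with its initial annotation **y** over K cell types,
estimates each cell's probability of being mislabelled, and reassigns
likely-mislabelled cells to their most probable type — fine-tuning an
existing annotation rather than producing one from scratch. It is aimed at
anyone running scRNA-seq pipelines who wants to audit or polish a cell-type
assignment, and it ships with the simulation and evaluation harness used to
benchmark it.

## Method

1. **Dimension reduction.** log2(FPKM+1)-transformed, zero-filtered
   expression is reduced by PCA. With *d* the number of components needed
   to capture at least 70% of the variance, the retained count is

       M' = 10 if d < 10,   d if 10 ≤ d ≤ 20,   20 if d > 20.

2. **Mislabelling probability.** A probabilistic classifier trained on the
   annotated cells gives each cell

       ε_i = 1 − P(ŷ_i = y_i | x_i),

   the probability that its current label is wrong.

3. **Adaptive resampling.** For L iterations (default 3), the next
   training set is drawn per class, with replacement, with inclusion
   weight 1 − ε_i — suspected mislabelled cells are progressively excluded
   and the model trains on cleaner labels. The first iteration uses
   uniform weights.

4. **Ensemble reclassification.** The final weights draw B training sets
   (default 10); one model is fitted per set, their class-probability
   matrices are averaged, and each cell is reassigned to the arg-max class.

Base classifiers: an RBF-kernel SVM trained one-against-one with
Platt-calibrated, pairwise-coupled probabilities, or a random forest whose
class probability is the fraction of its 100 trees voting for the class.

Quality is measured by per-class **mean accuracy**,
(1/K) Σ_k (1/N_k) Σ_{s_i=k} I(ŷ_i = s_i), and by the **adjusted Rand
index** computed from the four pair-count categories over all cell pairs.

## Worked example

`examples/correct_simulated_labels.py` simulates 5 cell types × 100 cells
with 2,000 genes (a gene is differentially expressed in a type with
probability 0.1), flips 10% of each type's labels to the next type, and
runs the corrector:

```
kept 20 principal components (70% variance crossing at d=223, clamped to [10, 20])
baseline  mean accuracy 0.900, ARI 0.773
corrected mean accuracy 0.998, ARI 0.995
49 of 500 labels were changed
```

The baseline 0.900 is exactly what 10% injected noise costs; after
correction only one of the 50 flipped cells remains wrong. The other
examples demonstrate the mislabelling-probability signal on planted
outliers and the difference between pooled accuracy, class-balanced mean
accuracy and ARI on an imbalanced annotation.

The same pipeline is available from the shell:

```sh
relabeler simulate --types 5 --cells-per-type 100 --genes 2000 --rho 0.1 --seed 7 --out-prefix sim
relabeler run --expr sim_matrix.csv --labels sim_noisy.csv --classifier svm --ensemble 10 --iters 3 --seed 8 --out corrected.csv
relabeler evaluate --truth sim_truth.csv --pred corrected.csv --out metrics.json
```

Matrices are CSV/TSV (genes × cells by default; `--orientation` overrides)
or Matrix Market with `.rows`/`.cols` sidecar name files. Runs with a
fixed `--seed` are byte-identical.

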