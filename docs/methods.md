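# Methods

## Problem and model

Given a cells × genes expression matrix in an FPKM-like unit and an
initial per-cell annotation over K cell types that may contain label
noise at rate ρ, the pipeline treats annotation correction as learning
under class-label noise. A probabilistic classifier trained on the noisy
labels assigns each cell a mislabelling probability
ε_i = 1 − P(ŷ_i = y_i | x_i); adaptively resampling the training set with
inclusion weight 1 − ε_i over successive iterations concentrates training
on cells whose labels are probably right, and a final ensemble reassigns
every cell to its arg-max class. The approach assumes (i) mislabelled
cells are a minority within each type (it provably breaks at ρ = 0.5,
where "wrong" labels are as common as right ones — the tests assert only
valid output there, not improvement); (ii) types are separable in the
retained principal-component space; and (iii) mislabelling is random
within a type — nonrandom noise concentrated at decision boundaries, and
strongly imbalanced type sizes, are outside the model.

## Pipeline stages and parameters

**Gene filter** (`zero_fraction_cutoff`, default 0.80). Genes whose
fraction of zero-valued cells strictly exceeds the cutoff are removed.
"Missing" means an expression value of exactly 0: FPKM tables are dense
and carry zeros, not NA. The filter runs before the log transform; the
zero pattern is unchanged by the transform, so the order is fixed purely
for determinism.

**Log transform.** v ↦ log2(v + 1). The unit tag on the matrix prevents
accidental double transformation.

**PCA reduction** (`variance_threshold` 0.70, `pc_floor` 10, `pc_ceiling`
20). d is the smallest number of leading components whose cumulative
explained-variance ratio reaches the threshold (inclusive, "at least
70%"); the retained count M' is d clamped to [10, 20]. PCA runs on
column-centred, unscaled data — log expression is already variance-
stabilised, and no correlation-matrix variant is used. The full SVD
solver is used and each component's sign is fixed by forcing its
largest-magnitude loading positive, making scores identical across runs
and backends. Matrices too small to supply `pc_floor` components keep all
available components with a warning.

**Base classifiers.** The SVM is an RBF-kernel machine (C = 1,
γ = 1/(M'·Var(X)), the common "scale" default; neither is prescribed by
the method) trained one-against-one, with per-pair Platt sigmoid
calibration coupled into K-class probabilities by Wu–Lin–Weng pairwise
coupling — the standard behaviour of libsvm-style implementations. The
random forest uses 100 trees and √M' features per split; its class
probability is the fraction of trees casting a hard vote for the class,
so probabilities are exact multiples of 1/B (the vote-fraction reading of
the per-tree round(·): a tree votes, it does not contribute its leaf
frequencies). A model trained on a resample that lost some classes pads
its probability matrix with zero columns to the full class order.

**Adaptive resampling** (`adasampling_iters` L, default 3). Iteration 1
trains on a uniform-weight stratified bootstrap — the uniform special
case of the same sampler, so L = 1 degenerates to a single fit-predict.
Sampling is stratified by observed class with per-class size N_k, with
replacement, and weights 1 − ε_i normalised within each class:
stratification keeps every class represented in every training set,
which a plain weighted draw over all cells cannot guarantee once some
classes shrink. ε is recomputed each iteration from predictions on all N
cells, not only the sampled ones. A class whose weights are all zero
falls back to uniform weights with a warning. Each class needs at least
4 cells (resampling plus calibration headroom).

**Ensemble** (`ensemble_size` B, default 10). The final ε draws B
training sets; the B probability matrices are combined by unweighted
mean — the minimal consistent combination rule. B = 1 gives the
single-final-model variant. Arg-max ties (possible with vote-fraction
forests) keep the initial label when it participates in the tie,
otherwise take the first class in first-appearance order — conservative
by construction. An optional `min_prob` threshold leaves labels unchanged
below a confidence floor; it is off by default because the method
reclassifies all cells.

**Determinism.** One master seed derives every stream (simulator,
resampling, classifier internals) through `numpy.random.SeedSequence`;
fixed-seed CLI runs are byte-identical. Labels are opaque strings; the
internal integer coding is first-appearance order, so renaming classes
permutes nothing but the names in the output.

## Synthetic data generator

The generator emulates the statistical silhouette of group-structured
scRNA-seq count simulations: per-gene baseline mean from Gamma(0.6,
rate 0.3) (right-skewed, heavy mass of weakly expressed genes); per
(type, gene) differential expression with probability `de_prob` = 0.1,
applying a log-normal fold change (log-sd `de_logfc_scale` = 1.0);
per-cell library factor log-normal(0, 0.2); negative-binomial counts with
dispersion 0.5 (variance μ + 0.5μ²); and conversion to an FPKM-like scale
by per-cell total normalisation with uniform 1-kb pseudo gene lengths,
since a count simulation has no real transcript lengths. Benchmark
defaults are 100 cells per type and 10,000 genes (the acceptance
benchmark uses 2,000 genes, which preserves the per-type DE gene count
scale of de_prob × n_genes while keeping the run under a minute per
seed).

What it does **not** emulate: batch effects, dropout beyond
negative-binomial zeros, expression outliers, trajectories, real
transcript lengths, or empirically estimated parameters. Passing tests
therefore show the corrector recovers random label noise when types are
separable groups; they do not show performance on real tissues, where
published applications report smaller gains.

**Label noise** is the cyclic flip: within each type k, exactly
⌊ρ·N_k⌋ cells chosen uniformly without replacement are relabelled to the
next type in first-appearance order, the last wrapping to the first. The
exact (non-Bernoulli) count makes the baseline mean accuracy of the noisy
annotation exactly 1 − ρ whenever ρ·N_k is integral, which anchors the
benchmark baselines deterministically.

## Evaluation

Mean accuracy is the unweighted mean over the K truth classes of the
within-class fraction correct; K comes from the truth label set and a
predicted label outside it simply counts as wrong. The adjusted Rand
index is computed in pair-count form, ARI = 2(ad − bc)/((a+b)(b+d) +
(a+c)(c+d)) over the four pair categories; the counts come from the
contingency table (algebraically identical to the explicit pair loop,
verified against it and against an independent library implementation in
the tests). Degenerate denominators: identical degenerate partitions
(b = c = 0) score 1, any other zero denominator scores 0.

## Numerical and interface choices

On-disk matrices default to genes × cells, the prevailing scRNA-seq
convention, with an orientation flag; sparse input is Matrix Market plus
plain-text `.rows`/`.cols` name sidecars. Annotation files are
two-column CSV with a header; duplicated cell ids with conflicting
labels are an error, unknown ids warn and drop (or error in strict
mode), unannotated cells are an error. The cumulative-variance
comparison uses a 1e-12 slack so a spectrum crossing the threshold
exactly at a component is counted at that component.

## Known limitations

Per-class resampling ignores type-size imbalance and assumes
within-type-random mislabelling; correction degrades as ρ grows and
fails by construction at ρ = 0.5. The PCA step is the only embedding
offered. The simulator is a statistical stand-in, not a calibrated model
of any real dataset.
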