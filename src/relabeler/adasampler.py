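"""Multi-class adaptive resampling for label-noise correction.

Given component scores X and an initial (possibly noisy) annotation y over
K cell types, the sampler iterates:

1. Train a probabilistic base classifier on a class-stratified bootstrap of
   the annotated cells (iteration 1 uses uniform weights, "treating all
   cells with uniform probability of being selected").
2. Predict class probabilities for ALL cells and set each cell's
   mislabelling probability eps_i = 1 - P(yhat_i = y_i | x_i).
3. Resample the next training set with per-cell inclusion weight
   1 - eps_i, so suspected mislabelled cells are progressively excluded.

After L iterations (default 3) the final eps weights draw B independent
training sets; one model is fitted per set and their probability matrices
are averaged.  Each cell is reassigned to the arg-max class of the
averaged probabilities; ties keep the initial label when it participates
in the tie, else take the first class in class order.

Sampling is stratified by observed class with per-class size N_k, with
replacement: stratification keeps every class represented in every
training set, which a plain weighted draw over all cells does not
guarantee once some classes shrink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifiers import fit_classifier, predict_proba
from .data import CellAnnotation
from .preprocess import ReducedMatrix

__all__ = [
    "estimate_epsilon",
    "weighted_resample",
    "adasample",
    "reclassify",
    "CorrectionResult",
]


@dataclass
class CorrectionResult:
    """Outcome of a full reclassification run."""

    corrected: CellAnnotation
    ensemble_probs: np.ndarray      # (N, K), row-stochastic
    class_order: list[str]
    epsilon_final: np.ndarray       # (N,) mislabelling probabilities after L iters
    changed_mask: np.ndarray        # (N,) bool

    @property
    def n_changed(self) -> int:
        return int(self.changed_mask.sum())


def estimate_epsilon(
    probs: np.ndarray, y: CellAnnotation, class_order: list[str] | None = None
) -> np.ndarray:
    """Per-cell mislabelling probability eps_i = 1 - P(yhat_i = y_i | x_i)."""
    probs = np.asarray(probs, dtype=float)
    class_order = list(class_order) if class_order is not None else y.label_set
    if probs.shape != (y.n_cells, len(class_order)):
        raise ValueError("probability matrix shape does not match annotation")
    col = {lab: k for k, lab in enumerate(class_order)}
    try:
        idx = np.array([col[lab] for lab in y.labels])
    except KeyError as e:
        raise ValueError(f"label outside class order: {e.args[0]!r}") from None
    eps = 1.0 - probs[np.arange(y.n_cells), idx]
    return np.clip(eps, 0.0, 1.0)


def weighted_resample(
    y: CellAnnotation, eps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a stratified training multiset with inclusion weights 1 - eps.

    For every observed class k with N_k members, N_k indices are drawn with
    replacement, with probability proportional to 1 - eps_i within the
    class.  A class whose weights are all zero falls back to uniform
    weights with a warning.  Returns the sorted index array (a multiset).
    """
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (y.n_cells,):
        raise ValueError("eps must be one value per cell")
    codes = y.codes()
    picked: list[np.ndarray] = []
    for k in range(y.n_types):
        members = np.nonzero(codes == k)[0]
        if members.size == 0:
            continue
        w = 1.0 - eps[members]
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            warnings.warn(
                f"class {y.label_set[k]!r}: all inclusion weights are zero; "
                "falling back to uniform sampling",
                stacklevel=2,
            )
            w = np.ones_like(w)
        picked.append(rng.choice(members, size=members.size, replace=True, p=w / w.sum()))
    return np.sort(np.concatenate(picked))


def adasample(
    X: ReducedMatrix,
    y: CellAnnotation,
    classifier_kind: str = "svm",
    L: int = 3,
    rng: np.random.Generator | None = None,
    n_trees: int = 100,
) -> np.ndarray:
    """Run L adaptive-resampling iterations; return the final eps vector.

    Iteration 1 trains on a uniform-weight stratified bootstrap (the
    uniform special case of the weighted sampler); later iterations weight
    by the previous eps.  Predictions — and hence eps — are always
    computed on all N cells.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    if y.n_types < 2:
        raise ValueError("need at least 2 cell types")
    _, counts = np.unique(y.codes(), return_counts=True)
    if counts.min() < 4:
        raise ValueError(
            "every cell type needs at least 4 cells for resampling and "
            "probability calibration"
        )
    scores = X.scores
    labels_arr = np.asarray(y.labels, dtype=object)
    eps = np.zeros(y.n_cells)  # uniform weights on the first pass
    for _ in range(L):
        idx = weighted_resample(y, eps, rng)
        model = fit_classifier(
            classifier_kind,
            scores[idx],
            labels_arr[idx],
            class_order=y.label_set,
            seed=int(rng.integers(2**31)),
            n_trees=n_trees,
        )
        probs = predict_proba(model, scores)
        eps = estimate_epsilon(probs, y, y.label_set)
    return eps


def reclassify(
    X: ReducedMatrix,
    y: CellAnnotation,
    classifier_kind: str = "svm",
    L: int = 3,
    B_ensemble: int = 10,
    rng: np.random.Generator | None = None,
    n_trees: int = 100,
    min_prob: float | None = None,
) -> CorrectionResult:
    """Full correction: adaptive sampling, final ensemble, arg-max relabelling.

    ``B_ensemble=1`` is the single-model variant (one final training set).
    ``min_prob``, when given, leaves a cell's label unchanged if the
    ensemble's maximum probability falls below it.
    """
    if B_ensemble < 1:
        raise ValueError("B_ensemble must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    eps = adasample(X, y, classifier_kind, L=L, rng=rng, n_trees=n_trees)

    scores = X.scores
    labels_arr = np.asarray(y.labels, dtype=object)
    acc = np.zeros((y.n_cells, y.n_types))
    for _ in range(B_ensemble):
        idx = weighted_resample(y, eps, rng)
        model = fit_classifier(
            classifier_kind,
            scores[idx],
            labels_arr[idx],
            class_order=y.label_set,
            seed=int(rng.integers(2**31)),
            n_trees=n_trees,
        )
        acc += predict_proba(model, scores)
    ensemble_probs = acc / B_ensemble

    initial_codes = y.codes()
    corrected_codes = _argmax_keep_initial(ensemble_probs, initial_codes)
    if min_prob is not None:
        low = ensemble_probs.max(axis=1) < min_prob
        corrected_codes[low] = initial_codes[low]
    corrected_labels = [y.label_set[k] for k in corrected_codes]
    corrected = CellAnnotation(
        corrected_labels, list(y.cell_ids), label_set=list(y.label_set)
    )
    return CorrectionResult(
        corrected=corrected,
        ensemble_probs=ensemble_probs,
        class_order=list(y.label_set),
        epsilon_final=eps,
        changed_mask=corrected_codes != initial_codes,
    )


def _argmax_keep_initial(probs: np.ndarray, initial: np.ndarray) -> np.ndarray:
    """Row arg-max; exact ties keep the initial label if tied, else lowest index."""
    best = probs.max(axis=1)
    out = np.argmax(probs, axis=1)
    tied = probs == best[:, None]
    multi = tied.sum(axis=1) > 1
    for i in np.nonzero(multi)[0]:
        out[i] = initial[i] if tied[i, initial[i]] else int(np.argmax(tied[i]))
    return out
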