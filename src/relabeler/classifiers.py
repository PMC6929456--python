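"""Probabilistic base classifiers wrapped by the adaptive sampler.

Two base learners are provided:

* an RBF-kernel support vector machine trained one-against-one, with
  per-pair Platt sigmoid calibration P = 1/(1 + exp(A f(x) + B)) coupled
  into a K-class probability by pairwise coupling (Wu-Lin-Weng), as
  implemented by :class:`sklearn.svm.SVC` with ``probability=True``;
* a random forest whose class probability is the fraction of trees casting
  a hard vote for that class, P(k|x) = (1/B) sum_b round(h(x|theta_b)) —
  computed from per-tree predictions rather than sklearn's leaf-probability
  average, so probabilities are exact multiples of 1/B.

Models trained on a resample that lost some classes pad their probability
output with zero columns to the full class order, so downstream
mislabelling estimates always see K columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = ["FittedClassifier", "fit_svm", "fit_rf", "fit_classifier", "predict_proba"]


@dataclass
class FittedClassifier:
    """A trained probabilistic classifier over a fixed class order."""

    kind: str                    # "svm" | "rf"
    model: object                # fitted sklearn estimator
    class_order: list[str]       # full K-class order (may exceed trained classes)
    training_size: int

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        return predict_proba(self, scores)


def _check_training_labels(y: np.ndarray, min_per_class: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    small = classes[counts < min_per_class]
    if small.size:
        raise ValueError(
            f"classes with fewer than {min_per_class} training cells: "
            f"{small.tolist()}; the sampler must guarantee minimum class counts"
        )


def fit_svm(
    scores: np.ndarray,
    y: np.ndarray,
    class_order: list[str],
    seed: int | None = None,
) -> FittedClassifier:
    """Fit the Platt-calibrated RBF SVM.

    Every class present in ``y`` needs at least 2 members for the internal
    sigmoid calibration.  ``class_order`` is the full K-class order used
    for probability padding.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    _check_training_labels(y, min_per_class=2)
    # SVC(probability=True) is precisely the pairwise Platt + coupling scheme
    # this method calls for; silence sklearn's deprecation nudge towards the
    # one-vs-rest CalibratedClassifierCV, which is a different calibration.
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        model = SVC(
            kernel="rbf",
            C=1.0,
            gamma="scale",
            probability=True,
            decision_function_shape="ovo",
            random_state=seed,
        )
        model.fit(scores, y)
    return FittedClassifier("svm", model, list(class_order), len(y))


def fit_rf(
    scores: np.ndarray,
    y: np.ndarray,
    class_order: list[str],
    n_trees: int = 100,
    seed: int | None = None,
) -> FittedClassifier:
    """Fit the vote-fraction random forest (default 100 trees).

    Each tree trains on a bootstrap sample with sqrt(M') features
    considered per split.  Single-member classes are tolerated.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    _check_training_labels(y, min_per_class=1)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
    )
    model.fit(scores, y)
    return FittedClassifier("rf", model, list(class_order), len(y))


def fit_classifier(
    kind: str,
    scores: np.ndarray,
    y: np.ndarray,
    class_order: list[str],
    seed: int | None = None,
    n_trees: int = 100,
) -> FittedClassifier:
    if kind == "svm":
        return fit_svm(scores, y, class_order, seed=seed)
    if kind == "rf":
        return fit_rf(scores, y, class_order, n_trees=n_trees, seed=seed)
    raise ValueError(f"unknown classifier kind: {kind!r}")


def predict_proba(model: FittedClassifier, scores: np.ndarray) -> np.ndarray:
    """Row-stochastic (N, K) probability matrix over ``model.class_order``.

    Classes absent from the training subset get probability 0.
    """
    scores = np.asarray(scores, dtype=float)
    est = model.model
    if scores.ndim != 2 or scores.shape[1] != est.n_features_in_:
        raise ValueError(
            f"feature mismatch: model expects {est.n_features_in_} features, "
            f"got {scores.shape[1] if scores.ndim == 2 else 'non-2D'}"
        )
    if model.kind == "rf":
        # hard per-tree votes: fraction of trees voting for each class
        trained = list(est.classes_)
        raw = np.zeros((scores.shape[0], len(trained)))
        for tree in est.estimators_:
            votes = np.argmax(tree.predict_proba(scores), axis=1)
            raw[np.arange(scores.shape[0]), votes] += 1.0
        raw /= len(est.estimators_)
    else:
        trained = list(est.classes_)
        raw = est.predict_proba(scores)

    full = np.zeros((scores.shape[0], len(model.class_order)))
    col = {lab: k for k, lab in enumerate(model.class_order)}
    for j, lab in enumerate(trained):
        full[:, col[lab]] = raw[:, j]
    return full
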