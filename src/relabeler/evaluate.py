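"""Evaluation metrics and the simulation benchmark harness.

Two metrics quantify agreement between an annotation and the ground truth:

* mean accuracy — the unweighted mean over the K truth cell types of the
  within-type fraction of correctly labelled cells,

      (1/K) * sum_k (1/N_k) * sum_{s_i = k} I(yhat_i = s_i),

  insensitive to pooled class-size imbalance (a huge class cannot mask
  errors in small ones, and vice versa);

* the adjusted Rand index in pair-count form.  Over all N(N-1)/2 cell
  pairs, let a = pairs co-typed in both lists, b = co-typed only in the
  first, c = co-typed only in the second, d = co-typed in neither; then

      ARI = 2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d)).

  The pair counts are computed from the contingency table (algebraically
  identical to the explicit pair loop, at O(N + K^2) cost).  Degenerate
  denominator: identical degenerate partitions (b = c = 0) give 1,
  otherwise 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adasampler import reclassify
from .config import derive_seeds
from .data import CellAnnotation
from .preprocess import preprocess
from .synthesize import SimulationConfig, inject_label_noise, simulate_expression

__all__ = [
    "mean_accuracy",
    "adjusted_rand_index",
    "evaluation_report",
    "EvaluationReport",
    "benchmark",
]


def mean_accuracy(pred: CellAnnotation, truth: CellAnnotation) -> float:
    """Unweighted mean over truth classes of the within-class accuracy.

    K is the number of distinct truth classes; predicted labels outside
    the truth label set simply count as wrong.
    """
    if pred.cell_ids != truth.cell_ids:
        raise ValueError("annotations are not aligned")
    t = np.asarray(truth.labels, dtype=object)
    p = np.asarray(pred.labels, dtype=object)
    accs = []
    for k in truth.label_set:
        members = t == k
        if not members.any():
            raise ValueError(f"empty truth class: {k!r}")
        accs.append(float(np.mean(p[members] == k)))
    return float(np.mean(accs))


def per_class_accuracy(pred: CellAnnotation, truth: CellAnnotation) -> dict[str, float]:
    t = np.asarray(truth.labels, dtype=object)
    p = np.asarray(pred.labels, dtype=object)
    return {k: float(np.mean(p[t == k] == k)) for k in truth.label_set}


def _pair_counts(a_codes: np.ndarray, b_codes: np.ndarray) -> tuple[int, int, int, int]:
    """Pair counts (a, b, c, d) over all unordered cell pairs, via contingency."""
    n = a_codes.size
    ka, kb = a_codes.max() + 1, b_codes.max() + 1
    cont = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(cont, (a_codes, b_codes), 1)

    def comb2(x):
        return x * (x - 1) // 2

    a = int(comb2(cont).sum())
    same_a = int(comb2(cont.sum(axis=1)).sum())   # a + b
    same_b = int(comb2(cont.sum(axis=0)).sum())   # a + c
    total = int(comb2(np.int64(n)))
    b = same_a - a
    c = same_b - a
    d = total - a - b - c
    return a, b, c, d


def adjusted_rand_index(a_labels: CellAnnotation, b_labels: CellAnnotation) -> float:
    """Chance-corrected pair-count agreement between two partitions."""
    if a_labels.cell_ids != b_labels.cell_ids:
        raise ValueError("annotations are not aligned")
    if a_labels.n_cells < 2:
        raise ValueError("ARI needs at least 2 cells")
    a, b, c, d = _pair_counts(a_labels.codes(), b_labels.codes())
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * d - b * c) / denom


@dataclass
class EvaluationReport:
    """Agreement of a (possibly corrected) annotation with the truth."""

    mean_accuracy: float
    ari: float
    per_class_accuracy: dict[str, float]
    n_changed: int
    confusion: pd.DataFrame  # truth classes x predicted labels, counts

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "ari": self.ari,
            "per_class": self.per_class_accuracy,
            "n_changed": self.n_changed,
        }


def evaluation_report(
    pred: CellAnnotation,
    truth: CellAnnotation,
    original: CellAnnotation | None = None,
) -> EvaluationReport:
    """Full agreement report; ``original`` sets the changed-cell count."""
    t = np.asarray(truth.labels, dtype=object)
    p = np.asarray(pred.labels, dtype=object)
    pred_classes = sorted(set(pred.labels) | set(truth.label_set))
    conf = pd.DataFrame(
        0, index=list(truth.label_set), columns=pred_classes, dtype=int
    )
    for ti, pi in zip(t, p):
        conf.loc[ti, pi] += 1
    n_changed = (
        0
        if original is None
        else int(sum(o != q for o, q in zip(original.labels, pred.labels)))
    )
    return EvaluationReport(
        mean_accuracy=mean_accuracy(pred, truth),
        ari=adjusted_rand_index(pred, truth),
        per_class_accuracy=per_class_accuracy(pred, truth),
        n_changed=n_changed,
        confusion=conf,
    )


def benchmark(
    cfg: SimulationConfig,
    rho_grid: list[float],
    classifier_kinds: list[str] = ("svm",),
    repeats: int = 10,
    seed: int | None = None,
    L: int = 3,
    B_ensemble: int = 10,
) -> pd.DataFrame:
    """Benchmark correction quality over a noise-rate grid.

    For each (rho, classifier, repeat), a fresh matrix is simulated, noise
    injected, the corrector run, and baseline vs corrected mean accuracy
    and ARI recorded.  Returns a long-format frame with one row per run.
    """
    rows = []
    seeds = derive_seeds(seed, repeats)
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        expr, truth, _ = simulate_expression(cfg, rng)
        reduced = preprocess(expr)
        for rho in rho_grid:
            noisy, _ = inject_label_noise(truth, rho, rng)
            base_acc = mean_accuracy(noisy, truth)
            base_ari = adjusted_rand_index(noisy, truth)
            for kind in classifier_kinds:
                result = reclassify(
                    reduced, noisy, kind, L=L, B_ensemble=B_ensemble, rng=rng
                )
                rows.append(
                    {
                        "rho": rho,
                        "classifier": kind,
                        "repeat": rep,
                        "seed": s,
                        "baseline_accuracy": base_acc,
                        "corrected_accuracy": mean_accuracy(result.corrected, truth),
                        "baseline_ari": base_ari,
                        "corrected_ari": adjusted_rand_index(result.corrected, truth),
                        "n_changed": result.n_changed,
                    }
                )
    return pd.DataFrame(rows)
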