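"""Preprocessing: log transform, zero-heavy gene removal, PCA reduction.

A "missing value" in an FPKM-style matrix is an expression value of exactly
zero (dense FPKM tables carry zeros, not NA); the gene filter removes genes
whose fraction of zero-valued cells STRICTLY exceeds the cutoff.

The number of retained principal components M' is the number of components
d needed to capture at least the variance threshold (default 70%), clamped
to [pc_floor, pc_ceiling] (defaults 10 and 20)::

    M' = 10  if d < 10
    M' = d   if 10 <= d <= 20
    M' = 20  if d > 20

PCA runs on column-centred (not unit-scaled) data; log-transformed
expression is already variance-stabilised.  Component signs are fixed by
forcing the largest-magnitude loading of each component to be positive, so
scores are reproducible across linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .config import RunConfig
from .data import RAW_UNITS, ExpressionMatrix

__all__ = [
    "log_transform",
    "filter_genes",
    "select_num_pcs",
    "reduce",
    "ReducedMatrix",
]


@dataclass
class ReducedMatrix:
    """Principal-component scores of a preprocessed expression matrix."""

    scores: np.ndarray          # (n_cells, selected_pcs)
    selected_pcs: int           # M'
    explained_ratios: np.ndarray  # per-component variance fractions, all components
    d: int                      # components needed to reach the variance threshold
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


def log_transform(X: ExpressionMatrix, force: bool = False) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1).

    Refuses matrices whose ``unit_tag`` is not a raw unit unless ``force``:
    double-transforming silently would corrupt the analysis.
    """
    if X.unit_tag not in RAW_UNITS and not force:
        raise ValueError(
            f"matrix tagged '{X.unit_tag}' looks already transformed; "
            "pass force=True to transform anyway"
        )
    if np.any(X.values < 0):
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(
        np.log2(X.values + 1.0),
        list(X.cell_ids),
        list(X.gene_ids),
        unit_tag="log2FPKM1",
    )


def filter_genes(X: ExpressionMatrix, cutoff: float = 0.80) -> ExpressionMatrix:
    """Drop genes whose zero fraction across cells strictly exceeds ``cutoff``.

    Gene order of the survivors is preserved; the cell set is unchanged.
    A gene zero in exactly ``cutoff * n_cells`` cells is retained.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    zero_frac = np.mean(X.values == 0, axis=0)
    keep = zero_frac <= cutoff
    if not keep.any():
        raise ValueError(
            "gene filter removed every gene; raise the zero-fraction cutoff"
        )
    return X.subset_genes(keep)


def select_num_pcs(
    explained_ratios: np.ndarray,
    threshold: float = 0.70,
    floor: int = 10,
    ceiling: int = 20,
) -> int:
    """Number of components to retain: crossing point clamped to [floor, ceiling].

    ``d`` is the smallest number of leading components whose cumulative
    explained-variance ratio reaches the threshold (inclusive comparison:
    "at least").  If the cumulative ratio never reaches the threshold,
    d is the full length, then clamped.
    """
    ratios = np.asarray(explained_ratios, dtype=float)
    if ratios.ndim != 1 or ratios.size == 0:
        raise ValueError("explained_ratios must be a non-empty 1-D vector")
    cum = np.cumsum(ratios)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    d = int(reached[0]) + 1 if reached.size else ratios.size
    return int(min(max(d, floor), ceiling))


def reduce(X: ExpressionMatrix, cfg: RunConfig | None = None) -> ReducedMatrix:
    """PCA-reduce a preprocessed matrix to its top M' component scores.

    Expects log-transformed, gene-filtered input with at least 3 cells.
    When fewer than ``pc_floor`` components exist (tiny matrices), all
    available components are kept with a warning.
    """
    cfg = cfg or RunConfig()
    n, m = X.values.shape
    if n < 3:
        raise ValueError("PCA reduction needs at least 3 cells")
    max_comp = min(n, m)
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(X.values)
    ratios = pca.explained_variance_ratio_

    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.zeros(pca.components_.shape[0], dtype=bool)
    for j, comp in enumerate(pca.components_):
        i = np.argmax(np.abs(comp))
        flip[j] = comp[i] < 0
    scores[:, flip] *= -1.0

    d_raw = select_num_pcs(ratios, cfg.variance_threshold, floor=1, ceiling=max_comp)
    m_prime = select_num_pcs(
        ratios, cfg.variance_threshold, cfg.pc_floor, cfg.pc_ceiling
    )
    if max_comp < cfg.pc_floor:
        warnings.warn(
            f"only {max_comp} components available (< floor {cfg.pc_floor}); "
            "keeping all of them",
            stacklevel=2,
        )
        m_prime = max_comp
    m_prime = min(m_prime, max_comp)
    return ReducedMatrix(
        scores=scores[:, :m_prime],
        selected_pcs=m_prime,
        explained_ratios=ratios,
        d=d_raw,
        cell_ids=list(X.cell_ids),
    )


def preprocess(
    X: ExpressionMatrix,
    cfg: RunConfig | None = None,
    do_filter: bool = True,
    do_log: bool = True,
) -> ReducedMatrix:
    """Full preprocessing chain: gene filter, log transform, PCA reduction."""
    cfg = cfg or RunConfig()
    if do_filter:
        X = filter_genes(X, cfg.zero_fraction_cutoff)
    if do_log:
        X = log_transform(X)
    return reduce(X, cfg)
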