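"""Core in-memory containers: expression matrices and cell annotations.

An expression matrix is always held cells x genes internally, whatever its
on-disk orientation was.  Cell-type labels are opaque strings; any integer
coding is internal, assigned in first-appearance order, and never exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix", "CellAnnotation"]

#: unit tags considered "raw" (non-negative, not yet log-transformed)
RAW_UNITS = frozenset({"FPKM", "counts", "simulated"})


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of non-negative expression values.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_genes)``.  Must be finite; must be
        non-negative when ``unit_tag`` is a raw unit ("FPKM", "counts",
        "simulated").
    cell_ids, gene_ids
        Unique identifiers for the rows and columns.
    unit_tag
        Free-text unit label, e.g. "FPKM" or "log2FPKM1".
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    unit_tag: str = "FPKM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell axis mismatch: {len(self.cell_ids)} ids for {n} rows"
            )
        if len(self.gene_ids) != m:
            raise ValueError(
                f"gene axis mismatch: {len(self.gene_ids)} ids for {m} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.unit_tag in RAW_UNITS and np.any(self.values < 0):
            raise ValueError(
                f"negative values in a matrix tagged as raw unit '{self.unit_tag}'"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the genes selected by boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return ExpressionMatrix(
            values=self.values[:, keep].copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=[g for g, k in zip(self.gene_ids, keep) if k],
            unit_tag=self.unit_tag,
        )


@dataclass
class CellAnnotation:
    """Per-cell categorical labels aligned with an :class:`ExpressionMatrix`.

    ``label_set`` is the declared set of cell types in first-appearance
    order; it is inferred from the labels when not supplied.
    """

    labels: list[str]
    cell_ids: list[str]
    label_set: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("labels and cell_ids differ in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in annotation")
        if self.label_set is None:
            self.label_set = first_appearance_order(self.labels)
        else:
            self.label_set = [str(x) for x in self.label_set]
            unknown = set(self.labels) - set(self.label_set)
            if unknown:
                raise ValueError(f"labels outside declared label set: {sorted(unknown)}")
        if len(set(self.label_set)) != len(self.label_set):
            raise ValueError("duplicate entries in label set")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def n_types(self) -> int:
        return len(self.label_set)

    def codes(self) -> np.ndarray:
        """Integer codes into ``label_set`` (internal use only)."""
        index = {lab: k for k, lab in enumerate(self.label_set)}
        return np.array([index[lab] for lab in self.labels], dtype=int)

    def check_aligned(self, expr: ExpressionMatrix) -> None:
        if self.cell_ids != expr.cell_ids:
            raise ValueError("annotation cell ids are not aligned with the matrix")


def first_appearance_order(labels) -> list[str]:
    """Distinct values of ``labels`` in order of first appearance."""
    seen: dict[str, None] = {}
    for x in labels:
        seen.setdefault(str(x), None)
    return list(seen)
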