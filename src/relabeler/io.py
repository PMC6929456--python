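"""Readers and writers for expression matrices, label files and results.

Dense matrices are CSV/TSV with an identifier header row and an identifier
first column.  Sparse matrices are Matrix Market files with plain-text
sidecars ``<path>.rows`` and ``<path>.cols`` holding one identifier per
line.  The on-disk default orientation is genes x cells, the common
scRNA-seq convention; pass ``orientation="cells_by_genes"`` to override.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import CellAnnotation, ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_result",
    "FormatError",
    "MissingAnnotationError",
]


class FormatError(ValueError):
    """An on-disk file does not match the declared format."""


class MissingAnnotationError(ValueError):
    """Cells present in the matrix lack an annotation."""


def read_expression(
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "genes_by_cells",
    unit_tag: str = "FPKM",
) -> ExpressionMatrix:
    """Read an expression matrix, returning it oriented cells x genes.

    Parameters
    ----------
    path
        Matrix file.  For ``fmt="mtx"`` the sidecars ``<path>.rows`` and
        ``<path>.cols`` must exist.
    fmt
        ``"csv"``, ``"tsv"`` or ``"mtx"``.
    orientation
        What the on-disk rows are: ``"genes_by_cells"`` (default) or
        ``"cells_by_genes"``.
    """
    path = Path(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        row_ids = [str(x) for x in df.index]
        col_ids = [str(x) for x in df.columns]
    elif fmt == "mtx":
        rows_file = path.with_name(path.name + ".rows")
        cols_file = path.with_name(path.name + ".cols")
        for side, axis in ((rows_file, "row"), (cols_file, "column")):
            if not side.exists():
                raise FormatError(f"missing {axis} sidecar file: {side}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_ids = rows_file.read_text().split()
        col_ids = cols_file.read_text().split()
        if len(row_ids) != values.shape[0]:
            raise FormatError(
                f"row sidecar lists {len(row_ids)} names but matrix has "
                f"{values.shape[0]} rows"
            )
        if len(col_ids) != values.shape[1]:
            raise FormatError(
                f"column sidecar lists {len(col_ids)} names but matrix has "
                f"{values.shape[1]} columns"
            )
    else:
        raise ValueError(f"unknown format: {fmt!r}")

    if orientation == "genes_by_cells":
        values = values.T
        cell_ids, gene_ids = col_ids, row_ids
    elif orientation == "cells_by_genes":
        cell_ids, gene_ids = row_ids, col_ids
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")

    return ExpressionMatrix(values, cell_ids, gene_ids, unit_tag=unit_tag)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "genes_by_cells",
) -> None:
    """Write a matrix in the given on-disk orientation (inverse of the reader)."""
    path = Path(path)
    if orientation == "genes_by_cells":
        values, rows, cols = expr.values.T, expr.gene_ids, expr.cell_ids
    else:
        values, rows, cols = expr.values, expr.cell_ids, expr.gene_ids
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(values, index=rows, columns=cols).to_csv(path, sep=sep)
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(values))
        path.with_name(path.name + ".rows").write_text("\n".join(rows) + "\n")
        path.with_name(path.name + ".cols").write_text("\n".join(cols) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_annotation(
    path: str | Path,
    expr: ExpressionMatrix,
    strict: bool = False,
    label_set: list[str] | None = None,
) -> CellAnnotation:
    """Read a two-column (cell_id, label) file, reordered to match ``expr``.

    The file must carry a header row; column names are free.  Cells in the
    file but not in the matrix are dropped with a warning (or rejected when
    ``strict``); cells in the matrix but absent from the file raise
    :class:`MissingAnnotationError`.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("annotation file needs two columns: cell_id, label")
    ids = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(str)

    dup = ids[ids.duplicated(keep=False)]
    if not dup.empty:
        conflicted = (
            pd.DataFrame({"id": ids, "lab": labels})
            .groupby("id")["lab"]
            .nunique()
        )
        bad = conflicted[conflicted > 1].index.tolist()
        if bad:
            raise ValueError(
                f"conflicting labels for duplicated cell ids: {bad}"
            )
        keep = ~ids.duplicated()
        ids, labels = ids[keep], labels[keep]

    mapping = dict(zip(ids, labels))
    known = set(expr.cell_ids)
    unknown = [i for i in ids if i not in known]
    if unknown:
        msg = f"{len(unknown)} annotated cells are not in the matrix: {unknown[:5]}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (dropped)", stacklevel=2)

    missing = [c for c in expr.cell_ids if c not in mapping]
    if missing:
        raise MissingAnnotationError(
            f"{len(missing)} cells lack an annotation, e.g. {missing[:5]}"
        )
    ordered = [mapping[c] for c in expr.cell_ids]
    return CellAnnotation(ordered, list(expr.cell_ids), label_set=label_set)


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    pd.DataFrame({"cell_id": ann.cell_ids, "label": ann.labels}).to_csv(
        path, index=False
    )


def write_result(
    original: CellAnnotation,
    corrected: CellAnnotation,
    probs: np.ndarray,
    class_order: list[str],
    path: str | Path,
) -> None:
    """Write the correction result table.

    Columns: cell_id, original_label, predicted_label, changed,
    max_probability, then one ``prob_<type>`` column per cell type, rows in
    input cell order.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (original.n_cells, len(class_order)):
        raise ValueError("probability matrix shape does not match inputs")
    if original.cell_ids != corrected.cell_ids:
        raise ValueError("original and corrected annotations are misaligned")
    out = pd.DataFrame(
        {
            "cell_id": original.cell_ids,
            "original_label": original.labels,
            "predicted_label": corrected.labels,
            "changed": [o != p for o, p in zip(original.labels, corrected.labels)],
            "max_probability": probs.max(axis=1),
        }
    )
    for k, name in enumerate(class_order):
        out[f"prob_{name}"] = probs[:, k]
    out.to_csv(path, index=False)
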