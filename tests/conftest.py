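import numpy as np
import pytest

from relabeler.data import CellAnnotation, ExpressionMatrix
from relabeler.preprocess import ReducedMatrix


def make_blob_scores(
    n_per_class: int,
    centers: np.ndarray,
    spread: float = 1.0,
    seed: int = 0,
) -> tuple[ReducedMatrix, CellAnnotation]:
    """Gaussian blobs in component space, one per class, as a ReducedMatrix."""
    centers = np.asarray(centers, dtype=float)
    k, dim = centers.shape
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(c, spread, size=(n_per_class, dim)) for c in centers]
    )
    n = k * n_per_class
    cell_ids = [f"c{i}" for i in range(n)]
    labels = [f"t{j}" for j in range(k) for _ in range(n_per_class)]
    reduced = ReducedMatrix(
        scores=scores,
        selected_pcs=dim,
        explained_ratios=np.full(dim, 1.0 / dim),
        d=dim,
        cell_ids=cell_ids,
    )
    return reduced, CellAnnotation(labels, cell_ids)


@pytest.fixture(scope="session")
def separable_blobs():
    """Three widely separated 10-D Gaussian classes, 40 cells each."""
    rng = np.random.default_rng(11)
    centers = rng.normal(0, 1, size=(3, 10)) * 12.0
    return make_blob_scores(40, centers, spread=1.0, seed=11)


@pytest.fixture
def tiny_expr():
    """A 4-cell x 5-gene raw matrix with a zero-heavy gene."""
    values = np.array(
        [
            [0.0, 1.0, 3.0, 0.0, 7.0],
            [0.0, 0.0, 1.0, 2.0, 0.0],
            [0.0, 3.0, 0.0, 1.0, 1.0],
            [1.0, 0.0, 1.0, 0.0, 2.0],
        ]
    )
    return ExpressionMatrix(
        values,
        cell_ids=["a", "b", "c", "d"],
        gene_ids=[f"g{i}" for i in range(5)],
        unit_tag="FPKM",
    )
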