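"""Group-structured scRNA-seq simulation and label-noise injection.

The generator emulates the statistical silhouette of Splatter-style
group simulations without reproducing Splatter's internals:

* per-gene baseline mean drawn from a gamma distribution;
* per (cell type, gene), with probability ``de_prob`` the gene is
  differentially expressed in that type, receiving a multiplicative
  log-normal fold change;
* per-cell library-size factor, log-normal;
* counts drawn negative-binomial around baseline x DE factor x library
  factor with a fixed dispersion;
* counts converted to an FPKM-like scale by per-cell total normalisation
  with uniform 1-kb pseudo gene lengths (the unit conversion is recorded
  in the run manifest).

Label noise is the cyclic per-class flip: within each cell type k,
floor(rho * N_k) cells chosen uniformly without replacement are relabelled
to the next type in first-appearance order (the last type wraps to the
first).  The flip count is exact rather than Bernoulli, so the baseline
mean accuracy of the noisy annotation is exactly 1 - rho when rho * N_k is
integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CellAnnotation, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "NoisySimulation",
    "simulate_expression",
    "inject_label_noise",
    "simulate_noisy",
]

# gamma baseline-mean hyperparameters (shape, rate): right-skewed means with
# a heavy mass of weakly expressed genes, as in real FPKM tables
_MEAN_SHAPE = 0.6
_MEAN_RATE = 0.3


@dataclass
class SimulationConfig:
    """Simulation parameters.

    Defaults are the benchmark conditions: 100 cells per type, 10,000
    genes, a gene is differentially expressed in a given type with
    probability 0.1.
    """

    n_types: int = 5
    cells_per_type: int = 100
    n_genes: int = 10_000
    de_prob: float = 0.1
    de_logfc_scale: float = 1.0
    dispersion: float = 0.5
    library_size_sigma: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if not 0 <= self.de_prob < 1:
            raise ValueError("de_prob must be in [0, 1)")
        if self.cells_per_type < 1 or self.n_genes < 1:
            raise ValueError("cells_per_type and n_genes must be positive")
        if self.dispersion <= 0 or self.de_logfc_scale < 0:
            raise ValueError("dispersion must be > 0 and de_logfc_scale >= 0")
        if self.library_size_sigma < 0:
            raise ValueError("library_size_sigma must be >= 0")


@dataclass
class NoisySimulation:
    """A simulated matrix with ground-truth and noise-injected annotations."""

    expr: ExpressionMatrix
    truth: CellAnnotation
    noisy: CellAnnotation
    flipped_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    rho: float = 0.0


def simulate_expression(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, CellAnnotation, np.ndarray]:
    """Simulate an FPKM-like matrix with known cell types.

    Returns ``(expr, truth, de_mask)`` where ``de_mask`` is the boolean
    (n_types, n_genes) matrix of genes differentially expressed per type.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    K, C, G = cfg.n_types, cfg.cells_per_type, cfg.n_genes
    N = K * C

    base_mean = rng.gamma(shape=_MEAN_SHAPE, scale=1.0 / _MEAN_RATE, size=G)
    de_mask = rng.random((K, G)) < cfg.de_prob
    log_fc = np.where(de_mask, rng.normal(0.0, cfg.de_logfc_scale, size=(K, G)), 0.0)
    type_mean = base_mean[None, :] * np.exp(log_fc)  # (K, G)

    lib = np.exp(rng.normal(0.0, cfg.library_size_sigma, size=N))  # per-cell factor
    type_of_cell = np.repeat(np.arange(K), C)
    mu = type_mean[type_of_cell] * lib[:, None]  # (N, G)

    # negative binomial: var = mu + dispersion * mu^2, i.e. size = 1/dispersion
    size = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(float)

    # FPKM-like scale: per-cell total normalisation, uniform 1-kb pseudo lengths
    totals = counts.sum(axis=1)
    totals[totals == 0] = 1.0
    fpkm = counts / totals[:, None] * 1e6

    labels = [f"type{k + 1}" for k in type_of_cell]
    cell_ids = [f"cell{i + 1}" for i in range(N)]
    gene_ids = [f"gene{g + 1}" for g in range(G)]
    expr = ExpressionMatrix(fpkm, cell_ids, gene_ids, unit_tag="simulated")
    truth = CellAnnotation(labels, cell_ids)
    return expr, truth, de_mask


def inject_label_noise(
    truth: CellAnnotation, rho: float, rng: np.random.Generator | None = None
) -> tuple[CellAnnotation, np.ndarray]:
    """Flip floor(rho * N_k) random cells per class to the cyclic next class.

    Returns ``(noisy, flipped_mask)``.  Requires ``0 <= rho <= 0.5``; a rho
    too small to flip any cell returns the truth unchanged with a warning.
    """
    if not 0 <= rho <= 0.5:
        raise ValueError("rho must be in [0, 0.5]")
    rng = rng if rng is not None else np.random.default_rng()
    K = truth.n_types
    codes = truth.codes()
    flipped = np.zeros(truth.n_cells, dtype=bool)
    new_codes = codes.copy()
    if K >= 2 and rho > 0:
        for k in range(K):
            members = np.nonzero(codes == k)[0]
            n_flip = int(np.floor(rho * members.size))
            if n_flip == 0:
                continue
            chosen = rng.choice(members, size=n_flip, replace=False)
            new_codes[chosen] = (k + 1) % K
            flipped[chosen] = True
    if not flipped.any():
        warnings.warn(
            "rho too small to flip any cell in any class; labels unchanged",
            stacklevel=2,
        )
    noisy = CellAnnotation(
        [truth.label_set[c] for c in new_codes],
        list(truth.cell_ids),
        label_set=list(truth.label_set),
    )
    return noisy, flipped


def simulate_noisy(
    cfg: SimulationConfig, rho: float, rng: np.random.Generator | None = None
) -> NoisySimulation:
    """Convenience: simulate a matrix and inject cyclic label noise."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    expr, truth, _ = simulate_expression(cfg, rng)
    noisy, flipped = inject_label_noise(truth, rho, rng)
    return NoisySimulation(expr=expr, truth=truth, noisy=noisy, flipped_mask=flipped, rho=rho)
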