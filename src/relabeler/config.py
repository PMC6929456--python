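"""Run configuration and deterministic seed derivation.

One master seed deterministically derives every random stream the pipeline
uses (simulator, resampling, classifier internals), so a fixed-seed run is
bit-reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RunConfig", "derive_seeds", "spawn_rng"]


@dataclass
class RunConfig:
    """Parameters of a label-correction run.

    Attributes
    ----------
    classifier
        Base classifier wrapped by the adaptive sampler: ``"svm"``
        (RBF kernel, Platt-calibrated probabilities) or ``"rf"``
        (vote-fraction random forest).
    ensemble_size
        Number of final models whose probability matrices are averaged
        (``B``); 1 gives the single-model variant.
    adasampling_iters
        Number of adaptive resampling iterations (``L``).
    variance_threshold
        Fraction of total variance the retained principal components must
        capture before clamping.
    pc_floor, pc_ceiling
        Clamp bounds on the number of retained components.
    zero_fraction_cutoff
        Genes whose fraction of zero values strictly exceeds this are
        dropped before the log transform.
    seed
        Master seed; ``None`` means non-reproducible entropy.
    orientation
        On-disk matrix orientation for readers.
    """

    classifier: str = "svm"
    ensemble_size: int = 10
    adasampling_iters: int = 3
    variance_threshold: float = 0.70
    pc_floor: int = 10
    pc_ceiling: int = 20
    zero_fraction_cutoff: float = 0.80
    seed: int | None = None
    orientation: str = "genes_by_cells"

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "rf"):
            raise ValueError("classifier must be 'svm' or 'rf'")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.pc_floor > self.pc_ceiling:
            raise ValueError("pc_floor must not exceed pc_ceiling")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.adasampling_iters < 1:
            raise ValueError("adasampling_iters must be >= 1")
        if not 0 < self.zero_fraction_cutoff <= 1:
            raise ValueError("zero_fraction_cutoff must be in (0, 1]")
        if self.orientation not in ("cells_by_genes", "genes_by_cells"):
            raise ValueError(
                "orientation must be 'cells_by_genes' or 'genes_by_cells'"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def derive_seeds(master: int | None, n: int) -> list[int]:
    """Derive ``n`` independent stream seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def spawn_rng(rng: np.random.Generator) -> np.random.Generator:
    """A child generator whose stream is a deterministic function of ``rng``."""
    return np.random.default_rng(int(rng.integers(2**31)))
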