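"""Seeded three-class synthetic feature tables.

Emulates the statistical structure of headband-exported EEG feature CSVs:
balanced negative/neutral/positive classes, correlated numeric features
(windowed statistics from the same electrode co-vary, hence a block
covariance), and class-dependent mean shifts on a class-specific subset of
feature blocks with controllable separability.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import CLASS_NAMES, FeatureTable


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-dataset parameters.

    separability is the between-class mean shift in within-class
    standard-deviation units; 0 means the three class-conditional
    distributions are identical.
    """

    n_per_class: int = 200
    p: int = 64
    separability: float = 2.0
    block_size: int = 8
    block_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.p < 1 or self.block_size < 1:
            raise ValueError("n_per_class, p and block_size must be positive")
        if self.separability < 0:
            raise ValueError("separability must be nonnegative")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")


def _block_sizes(p: int, block_size: int) -> list[int]:
    sizes = [block_size] * (p // block_size)
    if p % block_size:
        sizes.append(p % block_size)
    return sizes


def generate_dataset(config: GeneratorConfig) -> FeatureTable:
    """Draw a balanced 3-class table; same config + seed is bitwise identical.

    Features come in equicorrelated Gaussian blocks (correlation block_rho
    within a block, 0 between blocks, unit variances).  Each class receives
    a mean shift of magnitude `separability` on its own random subset of
    blocks, with blocks assigned to classes disjointly so every class has
    discriminative features.
    """
    rng = np.random.default_rng(config.seed)
    n_classes = len(CLASS_NAMES)
    sizes = _block_sizes(config.p, config.block_size)
    n_blocks = len(sizes)

    # Disjoint block-to-class assignment (round robin over a random order).
    block_order = rng.permutation(n_blocks)
    block_class = np.full(n_blocks, -1, dtype=int)
    for rank, b in enumerate(block_order):
        block_class[b] = rank % n_classes

    # Equicorrelated block factorization: x = sqrt(rho)*shared + sqrt(1-rho)*own.
    n_total = n_classes * config.n_per_class
    values = np.empty((n_total, config.p))
    col = 0
    for b, size in enumerate(sizes):
        shared = rng.standard_normal((n_total, 1))
        own = rng.standard_normal((n_total, size))
        block = np.sqrt(config.block_rho) * shared + np.sqrt(1.0 - config.block_rho) * own
        values[:, col:col + size] = block
        col += size

    labels = np.repeat(np.arange(n_classes), config.n_per_class)

    # Class-specific mean shifts, in within-class sd units (unit variances here).
    if config.separability > 0:
        col = 0
        for b, size in enumerate(sizes):
            k = block_class[b]
            values[labels == k, col:col + size] += config.separability
            col += size

    perm = rng.permutation(n_total)
    names = [f"feat_{j:04d}" for j in range(config.p)]
    return FeatureTable(values[perm], names, labels[perm])
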