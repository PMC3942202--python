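"""Synthetic expression-like data with the structure the method assumes.

Two generators:

* ``generate_subspace_data`` — k classes, each spanning a low-dimensional
  linear subspace of gene space (the sparse-representation premise that
  a sample lies in the span of its class's training samples), plus dense
  Gaussian noise and sparse gross corruption (the E term of the
  decomposition model).
* ``generate_de_genes_data`` — a planted differential-expression design
  for testing BW gene ranking: a subset of genes receives class-specific
  mean shifts, the rest are pure noise.

Both are fully reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .io import ExpressionMatrix

__all__ = ["SubspaceSimConfig", "generate_subspace_data",
           "generate_de_genes_data"]


@dataclass(frozen=True)
class SubspaceSimConfig:
    """Defaults are the study conditions used throughout the test suite:
    three classes on mutually orthogonal 4-dimensional subspaces of a
    300-gene space, 30 samples per class, optionally corrupted."""

    n_classes: int = 3
    subspace_dim: int = 4
    n_genes: int = 300
    n_per_class: int = 30
    noise_sd: float = 0.0
    corrupt_frac: float = 0.0
    corrupt_magnitude: float = 0.5
    orthogonal_classes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise InvalidParameterError("need at least 2 classes")
        if self.subspace_dim < 1 or self.subspace_dim >= self.n_genes:
            raise InvalidParameterError(
                f"subspace_dim must be in [1, n_genes), got {self.subspace_dim}")
        if self.n_per_class < 1:
            raise InvalidParameterError("n_per_class must be >= 1")
        if not (0 <= self.corrupt_frac < 1):
            raise InvalidParameterError(
                f"corrupt_frac must be in [0, 1), got {self.corrupt_frac}")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if (self.orthogonal_classes
                and self.n_classes * self.subspace_dim > self.n_genes):
            raise InvalidParameterError(
                "orthogonal class bases need n_classes*subspace_dim <= n_genes")


def generate_subspace_data(config: SubspaceSimConfig):
    """Draw a union-of-subspaces expression matrix.

    Returns ``(ExpressionMatrix, labels, truth)`` where truth records the
    class bases, the clean matrix, the dense noise and the corruption
    mask; clean + noise + corruption reconstructs the emitted values
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_genes
    k = config.n_classes
    d = config.subspace_dim
    npc = config.n_per_class
    n = k * npc

    if config.orthogonal_classes:
        G, _ = np.linalg.qr(rng.standard_normal((m, k * d)))
        bases = [G[:, c * d:(c + 1) * d] for c in range(k)]
    else:
        bases = [np.linalg.qr(rng.standard_normal((m, d)))[0] for _ in range(k)]

    cols, labels = [], []
    for c in range(k):
        coeffs = rng.standard_normal((d, npc))
        cols.append(bases[c] @ coeffs)
        labels.extend([f"class_{c}"] * npc)
    clean = np.concatenate(cols, axis=1)

    noise = (rng.normal(0.0, config.noise_sd, size=(m, n))
             if config.noise_sd > 0 else np.zeros((m, n)))

    corruption = np.zeros((m, n))
    mask = np.zeros((m, n), dtype=bool)
    n_corrupt = int(round(config.corrupt_frac * m * n))
    if n_corrupt:
        flat = rng.choice(m * n, size=n_corrupt, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_corrupt)
        corruption.flat[flat] = signs * config.corrupt_magnitude
        mask.flat[flat] = True

    values = clean + noise + corruption
    em = ExpressionMatrix(
        values=values,
        gene_ids=[f"gene_{i:04d}" for i in range(m)],
        sample_ids=[f"sample_{j:03d}" for j in range(n)],
    )
    truth = {
        "bases": bases,
        "clean": clean,
        "noise": noise,
        "corruption": corruption,
        "corruption_mask": mask,
        "config": config,
    }
    return em, labels, truth


def generate_de_genes_data(m: int = 2000, n_per_class: int = 30, k: int = 2,
                           n_informative: int = 100, shift: float = 2.0,
                           noise_sd: float = 1.0, seed: int = 0):
    """Planted differential-expression data for gene-selection tests.

    Each informative gene is up-shifted by ``shift`` in exactly one class
    (cycled over classes); all other gene/sample cells are N(0, noise_sd).
    Returns ``(ExpressionMatrix, labels, informative_gene_ids)``.
    """
    if n_informative > m:
        raise InvalidParameterError(
            f"n_informative ({n_informative}) exceeds n_genes ({m})")
    if k < 2 or n_per_class < 1 or m < 1 or n_informative < 0:
        raise InvalidParameterError("invalid size parameters")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = k * n_per_class
    values = rng.normal(0.0, noise_sd, size=(m, n))
    labels = [f"class_{c}" for c in range(k) for _ in range(n_per_class)]
    informative = np.sort(rng.choice(m, size=n_informative, replace=False))
    for rank, j in enumerate(informative):
        target = rank % k
        cols = slice(target * n_per_class, (target + 1) * n_per_class)
        values[j, cols] += shift
    gene_ids = [f"gene_{i:04d}" for i in range(m)]
    em = ExpressionMatrix(
        values=values, gene_ids=gene_ids,
        sample_ids=[f"sample_{j:03d}" for j in range(n)])
    return em, labels, [gene_ids[j] for j in informative]
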