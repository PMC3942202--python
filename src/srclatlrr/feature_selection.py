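"""Gene ranking by the ratio of between-class to within-class sums of
squares (the Dudoit–Fridlyand–Speed BW statistic) and top-g selection.

For gene j with class means m_kj and overall mean m_j:

    BW_j = sum_i (m_{c(i),j} - m_j)^2 / (sum_i (x_ij - m_{c(i),j})^2 + eps)

where both sums run over samples i with class c(i).  A tiny eps guards
genes with zero within-class scatter (maximally discriminative, ranked
first); a gene constant across all samples scores exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .io import ExpressionMatrix

__all__ = ["GeneScoreTable", "bw_ratio", "select_top_genes", "write_scores"]

_EPS = 1e-12


@dataclass
class GeneScoreTable:
    gene_ids: list
    bw_scores: np.ndarray
    ranking: np.ndarray        # gene indices sorted by descending score


def bw_ratio(X, labels) -> GeneScoreTable:
    """Score every gene by its BW ratio.

    X may be an :class:`ExpressionMatrix` or a genes x samples array.
    Ties rank stably in input-gene order.
    """
    if isinstance(X, ExpressionMatrix):
        values, gene_ids = X.values, list(X.gene_ids)
    else:
        values = np.asarray(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    labels = np.asarray([str(l) for l in labels])
    if labels.size != values.shape[1]:
        raise InvalidInputError(
            f"{labels.size} labels for {values.shape[1]} samples")
    classes = np.unique(labels)
    if classes.size < 2:
        raise InvalidInputError(
            f"need at least 2 classes to score genes, got {classes.tolist()}")
    overall = values.mean(axis=1)
    between = np.zeros(values.shape[0])
    within = np.zeros(values.shape[0])
    for c in classes:
        mask = labels == c
        nc = int(mask.sum())
        cmean = values[:, mask].mean(axis=1)
        between += nc * (cmean - overall) ** 2
        within += ((values[:, mask] - cmean[:, None]) ** 2).sum(axis=1)
    scores = np.where((between <= _EPS) & (within <= _EPS),
                      0.0, between / (within + _EPS))
    ranking = np.argsort(-scores, kind="stable")
    return GeneScoreTable(gene_ids=gene_ids, bw_scores=scores, ranking=ranking)


def select_top_genes(X, table: GeneScoreTable, g: int):
    """Keep the g top-ranked genes, rows emitted in ranked order.

    Returns (reduced ExpressionMatrix or array, selected gene ids).
    """
    if isinstance(X, ExpressionMatrix):
        values = X.values
        n_genes = values.shape[0]
    else:
        values = np.asarray(X, dtype=float)
        n_genes = values.shape[0]
    if not (1 <= g <= n_genes):
        raise InvalidParameterError(
            f"g must be in [1, {n_genes}], got {g}")
    if len(table.gene_ids) != n_genes:
        raise InvalidInputError("score table does not match matrix genes")
    top = table.ranking[:g]
    selected_ids = [table.gene_ids[i] for i in top]
    reduced = values[top, :]
    if isinstance(X, ExpressionMatrix):
        return (ExpressionMatrix(values=reduced, gene_ids=selected_ids,
                                 sample_ids=list(X.sample_ids)), selected_ids)
    return reduced, selected_ids


def write_scores(path, table: GeneScoreTable, delimiter: str = "\t") -> None:
    """TSV of (gene id, score, rank), one row per gene in ranked order."""
    with open(path, "w") as fh:
        fh.write(f"gene_id{delimiter}bw_score{delimiter}rank\n")
        for rank, idx in enumerate(table.ranking, start=1):
            fh.write(f"{table.gene_ids[idx]}{delimiter}"
                     f"{table.bw_scores[idx]:.17g}{delimiter}{rank}\n")
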