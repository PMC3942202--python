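"""srclatlrr: tumor classification from gene-expression matrices by
sparse representation over latent low-rank salient features.

The pipeline: decompose a column-normalized training matrix X into
principal features XZ, salient features LX and sparse noise E by latent
low-rank representation (inexact ALM); classify a test profile y by
l1-sparse coding of Ly over the dictionary D = LX and assigning the
class with the smallest reconstruction residual.
"""

from .classify import (ClassificationResult, TrainedModel, fit, load_model,
                       normalize_columns, predict, predict_batch, save_model)
from .errors import InvalidInputError, InvalidParameterError, SrcLatLrrError
from .evaluation import (CVConfig, CVReport, LambdaSweepTable, cross_validate,
                         lambda_sweep, stratified_kfold)
from .feature_selection import (GeneScoreTable, bw_ratio, select_top_genes,
                                write_scores)
from .io import (ExpressionMatrix, LabelVector, join_labels, read_expression,
                 read_labels, write_expression, write_labels)
from .latlrr import (LatLRRDecomposition, LatLRRParams, feasible_baseline,
                     fit_latlrr, latlrr_objective, load_decomposition,
                     save_decomposition)
from .proximal import SkinnySVD, skinny_svd, soft_threshold, svt
from .simulate import (SubspaceSimConfig, generate_de_genes_data,
                       generate_subspace_data)
from .sparse_coding import SparseCode, delta_mask, kkt_gap, solve_l1ls

__version__ = "0.1.0"

__all__ = [
    "ClassificationResult", "TrainedModel", "fit", "load_model",
    "normalize_columns", "predict", "predict_batch", "save_model",
    "InvalidInputError", "InvalidParameterError", "SrcLatLrrError",
    "CVConfig", "CVReport", "LambdaSweepTable", "cross_validate",
    "lambda_sweep", "stratified_kfold",
    "GeneScoreTable", "bw_ratio", "select_top_genes", "write_scores",
    "ExpressionMatrix", "LabelVector", "join_labels", "read_expression",
    "read_labels", "write_expression", "write_labels",
    "LatLRRDecomposition", "LatLRRParams", "feasible_baseline", "fit_latlrr",
    "latlrr_objective", "load_decomposition", "save_decomposition",
    "SkinnySVD", "skinny_svd", "soft_threshold", "svt",
    "SubspaceSimConfig", "generate_de_genes_data", "generate_subspace_data",
    "SparseCode", "delta_mask", "kkt_gap", "solve_l1ls",
]
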