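"""SRC and SRC-LatLRR classifiers.

Training: normalize the training columns to unit l2 norm; for
SRC-LatLRR additionally run the latent low-rank decomposition
X = XZ + LX + E and keep the salient-feature dictionary D = LX (for
plain SRC, L is the identity and D is the normalized training matrix).

Prediction: a test profile y is column-normalized, projected to Ly,
sparse-coded against D, and assigned the class whose coefficients
reconstruct Ly with the smallest residual r_i = ||Ly - D delta_i(x)||_2.
Ties are broken toward the lexicographically smallest class label.  The
projector L comes from the training fold only; test samples never enter
the decomposition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .io import ExpressionMatrix
from .latlrr import LatLRRParams, fit_latlrr
from .sparse_coding import SparseCode, delta_mask, solve_l1ls

__all__ = [
    "TrainedModel",
    "ClassificationResult",
    "normalize_columns",
    "fit",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]

_METHODS = ("src", "src-latlrr")


def normalize_columns(X, sample_ids=None):
    """Scale every column to unit l2 norm; returns (matrix, norms).

    A zero column is an error naming the offending sample — it carries
    no direction to represent.
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=0)
    zero = np.where(norms == 0)[0]
    if zero.size:
        which = (sample_ids[zero[0]] if sample_ids is not None
                 else f"column {zero[0]}")
        raise InvalidInputError(f"all-zero sample cannot be normalized: {which}")
    return X / norms, norms


@dataclass
class TrainedModel:
    """Everything needed to classify new profiles reproducibly."""

    method: str
    D: np.ndarray                     # dictionary, m x n
    L: np.ndarray                     # projector, m x m (identity for src)
    labels: list                      # class label per dictionary column
    gene_ids: list
    column_norms: np.ndarray          # normalization record of training columns
    classes: list = field(default_factory=list)   # sorted distinct labels
    latlrr_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != self.D.shape[1]:
            raise InvalidInputError("one label required per dictionary column")
        if not self.classes:
            self.classes = sorted(set(self.labels))


@dataclass
class ClassificationResult:
    predicted_class: str
    residuals: dict                   # class label -> r_i(y)
    sparse_code: SparseCode
    projected_test: np.ndarray
    sample_id: str | None = None


def fit(X_train: ExpressionMatrix, labels, method: str = "src-latlrr",
        latlrr_params: LatLRRParams | None = None) -> TrainedModel:
    """Train an SRC or SRC-LatLRR model on a labeled expression matrix."""
    if method not in _METHODS:
        raise InvalidInputError(f"method must be one of {_METHODS}, got {method!r}")
    labels = [str(l) for l in labels]
    if len(labels) != X_train.shape[1]:
        raise InvalidInputError(
            f"{len(labels)} labels for {X_train.shape[1]} training samples")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InvalidInputError(
            f"need at least 2 classes, got {classes}")
    Xn, norms = normalize_columns(X_train.values, X_train.sample_ids)
    m = Xn.shape[0]
    if method == "src":
        return TrainedModel(method=method, D=Xn, L=np.eye(m), labels=labels,
                            gene_ids=list(X_train.gene_ids),
                            column_norms=norms, classes=classes)
    params = latlrr_params or LatLRRParams(lambda_latlrr=0.1)
    dec = fit_latlrr(Xn, params)
    if not dec.converged:
        warnings.warn("LatLRR did not converge; model built from the last "
                      "iterate (converged=False)", RuntimeWarning)
    D = dec.L @ Xn
    meta = {
        "objective": dec.objective,
        "primal_residual": dec.primal_residual,
        "E_l1": dec.E_l1,
        "n_iter": dec.n_iter,
        "converged": dec.converged,
        "lambda_latlrr": params.lambda_latlrr,
    }
    return TrainedModel(method=method, D=D, L=dec.L, labels=labels,
                        gene_ids=list(X_train.gene_ids), column_norms=norms,
                        classes=classes, latlrr_meta=meta)


def predict(model: TrainedModel, y, lambda_src: float = 0.01,
            tol: float = 1e-6, sample_id: str | None = None) -> ClassificationResult:
    """Classify a single expression profile by minimum class residual."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size != model.D.shape[0]:
        raise InvalidInputError(
            f"test vector has {y.size} genes, model expects {model.D.shape[0]}"
            + (f" (sample {sample_id})" if sample_id else ""))
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("test vector contains non-finite entries")
    nrm = np.linalg.norm(y)
    if nrm == 0:
        raise InvalidInputError(
            "all-zero test vector cannot be classified"
            + (f" (sample {sample_id})" if sample_id else ""))
    yn = y / nrm
    Ly = model.L @ yn
    code = solve_l1ls(model.D, Ly, lambda_src=lambda_src, tol=tol)
    class_per_col = np.asarray(model.labels)
    residuals = {}
    for c in model.classes:
        xc = delta_mask(code.x, class_per_col, c)
        residuals[c] = float(np.linalg.norm(Ly - model.D @ xc))
    # argmin with ties toward the smallest class label (classes is sorted)
    predicted = min(model.classes, key=lambda c: (residuals[c], model.classes.index(c)))
    return ClassificationResult(predicted_class=predicted, residuals=residuals,
                                sparse_code=code, projected_test=Ly,
                                sample_id=sample_id)


def predict_batch(model: TrainedModel, Y, lambda_src: float = 0.01,
                  tol: float = 1e-6, sample_ids=None):
    """Column-wise application of :func:`predict`, order preserved."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    out = []
    for j in range(Y.shape[1]):
        sid = sample_ids[j] if sample_ids is not None else None
        out.append(predict(model, Y[:, j], lambda_src=lambda_src, tol=tol,
                           sample_id=sid))
    return out


def save_model(path, model: TrainedModel) -> None:
    """Persist a model to an .npz archive; predictions round-trip bit-exactly."""
    np.savez(
        path,
        method=model.method,
        D=model.D,
        L=model.L,
        labels=np.asarray(model.labels, dtype=object),
        gene_ids=np.asarray(model.gene_ids, dtype=object),
        column_norms=model.column_norms,
        classes=np.asarray(model.classes, dtype=object),
        latlrr_meta=json.dumps(model.latlrr_meta),
    )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=True) as z:
        return TrainedModel(
            method=str(z["method"]),
            D=z["D"],
            L=z["L"],
            labels=[str(l) for l in z["labels"]],
            gene_ids=[str(g) for g in z["gene_ids"]],
            column_norms=z["column_norms"],
            classes=[str(c) for c in z["classes"]],
            latlrr_meta=json.loads(str(z["latlrr_meta"])),
        )
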