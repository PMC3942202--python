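"""Stratified cross-validation and the lambda-sweep diagnostic.

Accuracy is pooled over folds (total correct / total samples), with
per-fold accuracies kept for transparency.  Gene selection, when
requested, is computed on the training fold only unless
``global_selection`` is set, and the trained model of a fold never sees
that fold's test samples.  The sweep reuses one fold assignment across
all lambda values so the accuracy / removed-noise curves isolate the
effect of lambda.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classify
from .errors import InvalidInputError, InvalidParameterError
from .feature_selection import bw_ratio, select_top_genes
from .io import ExpressionMatrix
from .latlrr import LatLRRParams

__all__ = ["CVConfig", "CVReport", "LambdaSweepTable", "stratified_kfold",
           "cross_validate", "lambda_sweep"]


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 10
    seed: int = 0
    method: str = "src-latlrr"
    lambda_latlrr: float = 0.1
    lambda_src: float = 0.01
    n_genes: int | None = None          # BW selection size; None = all genes
    global_selection: bool = False
    latlrr_max_iter: int = 1000
    latlrr_tol: float = 1e-6

    def __post_init__(self):
        if self.k_folds < 2:
            raise InvalidParameterError("k_folds must be >= 2")
        if self.method not in ("src", "src-latlrr"):
            raise InvalidParameterError(f"unknown method {self.method!r}")


@dataclass
class CVReport:
    fold_accuracies: list
    pooled_accuracy: float
    records: list                        # dicts: sample_id, true, predicted, fold
    config: dict
    fold_diagnostics: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tfold\ttrue_class\tpredicted_class\tcorrect\n")
            for r in self.records:
                fh.write(f"{r['sample_id']}\t{r['fold']}\t{r['true']}\t"
                         f"{r['predicted']}\t{int(r['true'] == r['predicted'])}\n")


@dataclass
class LambdaSweepTable:
    rows: list                           # dicts: lambda_latlrr, accuracy, mean_E_l1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lambda_latlrr\tpooled_accuracy\tmean_E_l1\n")
            for r in self.rows:
                fh.write(f"{r['lambda_latlrr']:.17g}\t{r['pooled_accuracy']:.17g}"
                         f"\t{r['mean_E_l1']:.17g}\n")


def stratified_kfold(labels, k: int, seed: int = 0):
    """Class-proportion-preserving folds; deterministic given seed.

    Returns a list of (train_indices, test_indices) arrays partitioning
    all samples.
    """
    labels = np.asarray([str(l) for l in labels])
    classes, counts = np.unique(labels, return_counts=True)
    smallest = classes[np.argmin(counts)]
    if k > counts.min():
        raise InvalidParameterError(
            f"k_folds={k} exceeds the size of the smallest class "
            f"({smallest!r}, {counts.min()} samples)")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in
            skf.split(np.zeros(labels.size), labels)]


def _fit_fold(X_train: ExpressionMatrix, train_labels, config: CVConfig):
    params = None
    if config.method == "src-latlrr":
        params = LatLRRParams(lambda_latlrr=config.lambda_latlrr,
                              tol=config.latlrr_tol,
                              max_iter=config.latlrr_max_iter)
    return classify.fit(X_train, train_labels, method=config.method,
                        latlrr_params=params)


def cross_validate(X: ExpressionMatrix, labels, config: CVConfig,
                   folds=None) -> CVReport:
    """Stratified k-fold cross-validation of SRC / SRC-LatLRR.

    ``folds`` may be passed to reuse a fixed assignment (the sweep does);
    by default they are derived from ``config.seed``.
    """
    labels = [str(l) for l in labels]
    if len(labels) != X.shape[1]:
        raise InvalidInputError(
            f"{len(labels)} labels for {X.shape[1]} samples")
    if folds is None:
        folds = stratified_kfold(labels, config.k_folds, config.seed)

    table_global = None
    if config.n_genes is not None and config.global_selection:
        table_global = bw_ratio(X, labels)

    labels_arr = np.asarray(labels)
    records, fold_acc, diagnostics = [], [], []
    for fold_id, (tr, te) in enumerate(folds):
        X_tr = ExpressionMatrix(values=X.values[:, tr],
                                gene_ids=list(X.gene_ids),
                                sample_ids=[X.sample_ids[i] for i in tr])
        y_tr = labels_arr[tr].tolist()
        X_te_vals = X.values[:, te]
        if config.n_genes is not None:
            table = table_global if table_global is not None else bw_ratio(X_tr, y_tr)
            X_tr, _ = select_top_genes(X_tr, table, config.n_genes)
            X_te_vals = X_te_vals[table.ranking[:config.n_genes], :]
        model = _fit_fold(X_tr, y_tr, config)
        results = classify.predict_batch(
            model, X_te_vals, lambda_src=config.lambda_src,
            sample_ids=[X.sample_ids[i] for i in te])
        correct = 0
        for i, res in zip(te, results):
            rec = {"sample_id": X.sample_ids[i], "fold": fold_id,
                   "true": labels_arr[i], "predicted": res.predicted_class}
            correct += int(rec["true"] == rec["predicted"])
            records.append(rec)
        fold_acc.append(correct / len(te))
        diag = {"fold": fold_id, "n_train": len(tr), "n_test": len(te)}
        if config.method == "src-latlrr":
            diag.update(model.latlrr_meta)
        diagnostics.append(diag)

    pooled = sum(r["true"] == r["predicted"] for r in records) / len(records)
    return CVReport(fold_accuracies=fold_acc, pooled_accuracy=pooled,
                    records=records, config=asdict(config),
                    fold_diagnostics=diagnostics)


def lambda_sweep(X: ExpressionMatrix, labels, lambdas, config: CVConfig) -> LambdaSweepTable:
    """One cross-validation per lambda plus the mean removed-noise level
    ``||E||_1`` across fold decompositions, rows in lambda order."""
    lambdas = [float(l) for l in lambdas]
    if not lambdas:
        raise InvalidParameterError("lambda grid is empty")
    if any(l <= 0 for l in lambdas):
        raise InvalidParameterError("lambda values must be positive")
    if any(b <= a for a, b in zip(lambdas, lambdas[1:])):
        raise InvalidParameterError("lambda grid must be strictly increasing")
    if config.method != "src-latlrr":
        raise InvalidParameterError(
            "the lambda sweep applies to method='src-latlrr' only")
    labels = [str(l) for l in labels]
    folds = stratified_kfold(labels, config.k_folds, config.seed)
    rows = []
    for lam in lambdas:
        cfg = CVConfig(**{**asdict(config), "lambda_latlrr": lam})
        report = cross_validate(X, labels, cfg, folds=folds)
        e_l1 = [d["E_l1"] for d in report.fold_diagnostics if "E_l1" in d]
        rows.append({"lambda_latlrr": lam,
                     "pooled_accuracy": report.pooled_accuracy,
                     "mean_E_l1": float(np.mean(e_l1))})
    return LambdaSweepTable(rows=rows)
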