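"""Readers and writers for expression matrices, labels and reports.

Expression files are delimited text (TSV or CSV, auto-detected): genes
are rows, samples are columns, the first column holds gene identifiers
and the header row holds sample identifiers.  Values are written with 17
significant digits so a write/read round trip is exact in double
precision.  Missing values are rejected — the decomposition has no
imputation step and silently propagating NaNs would corrupt it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "join_labels",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with row/column identifiers."""

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("expression values must be 2-d")
        m, n = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise InvalidInputError(
                f"id lengths ({len(self.gene_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {self.values.shape}")
        if m < 1 or n < 2:
            raise InvalidInputError(
                f"need at least 1 gene and 2 samples, got {m} x {n}")
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise InvalidInputError(f"duplicate gene ids: {dup_g[:5]}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise InvalidInputError(f"duplicate sample ids: {dup_s[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InvalidInputError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r} (missing values are "
                "not supported)")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)


@dataclass
class LabelVector:
    """Per-sample class labels, joined to a matrix by sample id."""

    sample_ids: list
    labels: list

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.sample_ids) != len(self.labels):
            raise InvalidInputError("sample_ids and labels differ in length")
        if not self.sample_ids:
            raise InvalidInputError("label vector is empty")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise InvalidInputError(f"duplicate sample ids in labels: {dup[:5]}")


def _duplicates(items):
    seen, dups = set(), []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path, delimiter: str | None = None,
                    transpose: bool = False) -> ExpressionMatrix:
    """Parse a delimited expression file (genes x samples by default).

    ``transpose=True`` accommodates sample-major files.  Errors name the
    offending id, cell or line where possible.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    delim = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"malformed file {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise InvalidInputError(f"{path}: no data rows/columns parsed")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                row = bad.index[0]
                line = df.index.get_loc(row) + 2   # header is line 1
                raise InvalidInputError(
                    f"{path}: non-numeric value {bad.iloc[0]!r} at gene "
                    f"{row!r}, sample {col!r} (line {line})")
            df[col] = pd.to_numeric(df[col])
    if transpose:
        df = df.T
    return ExpressionMatrix(values=df.to_numpy(dtype=float),
                            gene_ids=list(df.index.astype(str)),
                            sample_ids=list(df.columns.astype(str)))


def write_expression(path, em: ExpressionMatrix, delimiter: str = "\t") -> None:
    df = em.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_labels(path, delimiter: str | None = None) -> LabelVector:
    """Parse a two-column sample-id / class-label file.

    A header line whose first field is ``sample_id`` is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    delim = delimiter or _sniff_delimiter(path)
    sample_ids, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delim)
            if len(parts) != 2:
                raise InvalidInputError(
                    f"{path}: line {lineno} has {len(parts)} fields, "
                    "expected 2 (sample id, class label)")
            if lineno == 1 and parts[0].strip().lower() == "sample_id":
                continue
            sample_ids.append(parts[0].strip())
            labels.append(parts[1].strip())
    if not sample_ids:
        raise InvalidInputError(f"{path}: no label rows found")
    return LabelVector(sample_ids=sample_ids, labels=labels)


def write_labels(path, lv: LabelVector, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_id{delimiter}label\n")
        for sid, lab in zip(lv.sample_ids, lv.labels):
            fh.write(f"{sid}{delimiter}{lab}\n")


def join_labels(em: ExpressionMatrix, lv: LabelVector) -> list:
    """Labels reordered to match the matrix's sample order (join by id)."""
    mapping = dict(zip(lv.sample_ids, lv.labels))
    missing = [s for s in em.sample_ids if s not in mapping]
    if missing:
        raise InvalidInputError(
            f"samples missing from label file: {missing}")
    extra = [s for s in lv.sample_ids if s not in set(em.sample_ids)]
    if extra:
        raise InvalidInputError(
            f"label file contains unknown samples: {extra}")
    return [mapping[s] for s in em.sample_ids]


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
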