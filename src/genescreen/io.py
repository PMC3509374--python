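"""Core data containers and delimited-text I/O.

Expression data is a genes-by-samples matrix of real-valued expression
levels (arbitrary units, e.g. raw chip intensities).  Class membership of
the samples is a binary classification vector ``c`` with ``c_j = 1`` for
type-A samples and ``c_j = 0`` for type-B samples.  All downstream
statistics need at least two samples per class, and no missing values are
tolerated: the signal-to-noise statistic has no missing-data provision, so
incomplete matrices are rejected at load time rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClassVector",
    "GeneSelection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_selection",
    "read_selection",
]


def _detect_delimiter(path: Path) -> str:
    """Pick tab or comma from the first line (tab wins if both occur)."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValueError(
        f"{path}: could not detect a tab or comma delimiter in the header line"
    )


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {kind} identifier: {name!r}")
        seen.add(name)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes-by-samples expression matrix with identifier bookkeeping.

    Parameters
    ----------
    gene_ids : tuple of str
        Unique gene identifiers, one per row.
    sample_ids : tuple of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite real expression levels.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array (genes x samples)")
        object.__setattr__(self, "values", values)
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(self.sample_ids) != values.shape[1]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {values.shape[1]} columns"
            )
        if values.shape[0] < 1 or values.shape[1] < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class ClassVector:
    """Binary classification vector aligned to a matrix's sample order.

    ``labels[j] = 1`` marks sample ``j`` as type A, ``0`` as type B.
    Both classes must contain at least two samples so that within-class
    standard deviations are defined.
    """

    labels: np.ndarray
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8).ravel()
        object.__setattr__(self, "labels", labels)
        if self.sample_ids is not None:
            object.__setattr__(
                self, "sample_ids", tuple(str(s) for s in self.sample_ids)
            )
            if len(self.sample_ids) != labels.size:
                raise ValueError("sample_ids length does not match labels")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must contain only 0 and 1")
        n1 = int(labels.sum())
        n2 = labels.size - n1
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"each class needs >= 2 samples (got n1={n1}, n2={n2}); "
                "within-class standard deviations are undefined otherwise"
            )

    @property
    def m(self) -> int:
        return int(self.labels.size)

    @property
    def n1(self) -> int:
        return int(self.labels.sum())

    @property
    def n2(self) -> int:
        return self.m - self.n1

    def swapped(self) -> "ClassVector":
        """The same partition with class roles exchanged (1 <-> 0)."""
        return ClassVector(1 - self.labels, self.sample_ids)


@dataclass(frozen=True)
class GeneSelection:
    """Genes whose score magnitude reaches the selection threshold."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    threshold: float
    directions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        scores = np.asarray(self.scores, dtype=float).ravel()
        directions = np.asarray(self.directions, dtype=np.int8).ravel()
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "directions", directions)
        if not (len(self.gene_ids) == scores.size == directions.size):
            raise ValueError("gene_ids, scores and directions must align")
        if float(self.threshold) <= 0:
            raise ValueError("threshold must be positive")
        if scores.size:
            if np.any(np.abs(scores) < self.threshold):
                raise ValueError("every selected gene must satisfy |score| >= threshold")
            if np.any(directions != np.where(scores >= 0, 1, -1)):
                raise ValueError("directions inconsistent with score signs")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression matrix into genes-in-rows orientation.

    The header row holds sample identifiers and the first column gene
    identifiers (transposed when ``genes_in_rows`` is false).  The
    delimiter is auto-detected among tab and comma unless given.
    Duplicate identifiers, missing cells and non-numeric cells are load
    errors naming the offending identifier or cell.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "header")
    raw = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    ids = [str(i) for i in raw.index]
    _check_unique(ids, "row")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        cell = raw.iat[i, j]
        what = "missing" if (pd.isna(cell) or str(cell).strip() == "") else f"non-numeric ({cell!r})"
        raise ValueError(
            f"{path}: {what} value at row {ids[i]!r}, column {raw.columns[j]!r}"
        )
    # convert from the raw strings (not to_numeric's fast parser) so that
    # full-precision files round-trip bit-for-bit
    exact = pd.DataFrame(
        raw.to_numpy(dtype=float), index=numeric.index, columns=numeric.columns
    )
    frame = exact if genes_in_rows else exact.T
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix at full precision (round-trips bit-for-bit)."""
    frame = matrix.to_frame()
    frame.to_csv(path, sep=delimiter, index_label="gene_id", float_format="%.17g")


def read_labels(
    path: str | Path,
    positive_class: str,
    sample_ids: Sequence[str] | None = None,
    delimiter: str | None = None,
) -> ClassVector:
    """Read a two-column (sample_id, class) file into a ClassVector.

    Exactly two distinct class names are allowed; ``positive_class`` is
    encoded as 1.  When ``sample_ids`` is given (the matrix's sample
    order, which is canonical), the labels are reordered to match it and
    every matrix sample must be present exactly once.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    table = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if table.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (sample_id, class)")
    samples = [str(s).strip() for s in table.iloc[:, 0]]
    classes = [str(c).strip() for c in table.iloc[:, 1]]
    _check_unique(samples, "sample")
    class_names = sorted(set(classes))
    if len(class_names) != 2:
        raise ValueError(
            f"{path}: expected exactly 2 classes, found {len(class_names)}: {class_names}"
        )
    if positive_class not in class_names:
        raise ValueError(
            f"positive class {positive_class!r} not among classes {class_names}"
        )
    mapping = dict(zip(samples, classes))
    if sample_ids is not None:
        missing = [s for s in sample_ids if str(s) not in mapping]
        if missing:
            raise ValueError(f"{path}: no label for sample(s) {missing}")
        extra = [s for s in samples if s not in {str(t) for t in sample_ids}]
        if extra:
            raise ValueError(f"{path}: label(s) for unknown sample(s) {extra}")
        order = [str(s) for s in sample_ids]
    else:
        order = samples
    labels = np.array([1 if mapping[s] == positive_class else 0 for s in order],
                      dtype=np.int8)
    return ClassVector(labels, tuple(order))


def write_labels(
    labels: ClassVector,
    path: str | Path,
    class_names: tuple[str, str] = ("A", "B"),
    delimiter: str = "\t",
) -> None:
    if labels.sample_ids is None:
        raise ValueError("ClassVector has no sample identifiers to write")
    with open(path, "w", encoding="utf-8") as fh:
        for sid, lab in zip(labels.sample_ids, labels.labels):
            fh.write(f"{sid}{delimiter}{class_names[0] if lab == 1 else class_names[1]}\n")


def _format_score(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.6f}"


def write_selection(selection: GeneSelection, path: str | Path) -> None:
    """Write a selection report: gene_id, score, direction, threshold.

    Rows are ordered by descending ``|score|`` with ties broken by
    lexicographic gene id, so repeated runs produce identical files.
    Sentinel (infinite) scores are printed as ``inf`` / ``-inf`` tokens.
    """
    order = sorted(
        range(len(selection)),
        key=lambda i: (-abs(selection.scores[i]), selection.gene_ids[i]),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tscore\tdirection\tthreshold\n")
        for i in order:
            fh.write(
                f"{selection.gene_ids[i]}\t{_format_score(float(selection.scores[i]))}"
                f"\t{int(selection.directions[i]):+d}\t{selection.threshold:.6f}\n"
            )


def read_selection(path: str | Path, threshold: float | None = None) -> GeneSelection:
    """Read back a selection report written by :func:`write_selection`.

    A header-only report carries no threshold row, so ``threshold`` must
    then be supplied by the caller.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if len(table):
        threshold = float(table["threshold"].iloc[0])
    elif threshold is None:
        raise ValueError(f"{path}: empty selection report needs an explicit threshold")
    return GeneSelection(
        gene_ids=tuple(table["gene_id"]),
        scores=table["score"].to_numpy(dtype=float),
        threshold=threshold,
        directions=table["direction"].to_numpy(dtype=int),
    )
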