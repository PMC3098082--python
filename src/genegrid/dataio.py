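"""Reading, writing and validating two-class expression matrices.

The on-disk dialect is tab-delimited text: the first row holds the sample
ids (an optional corner cell such as ``gene_id`` is tolerated), an optional
second row starting with the token ``class`` carries one label per sample,
and every remaining row is a gene id followed by one numeric value per
sample.  Labels may instead come from a separate two-column
``sample_id<TAB>label`` file.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ExpressionDataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "split_by_class",
]

#: cell tokens treated as missing values
MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}


class DatasetFormatError(ValueError):
    """Raised when an input file violates the two-class matrix contract."""


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with a binary sample labelling.

    Parameters
    ----------
    matrix : ndarray of shape (n_genes, n_samples)
        Real-valued expression, all finite.
    gene_ids, sample_ids : list of str
        Unique identifiers matching the matrix dimensions.
    labels : list of str
        Exactly two distinct values, each occurring at least twice.
    positive_class : str, optional
        The class treated as "class 1" for up/down direction calls.
        Defaults to the lexicographically smaller label.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = [str(l) for l in self.labels]
        if self.matrix.ndim != 2:
            raise DatasetFormatError("expression matrix must be 2-dimensional")
        g, n = self.matrix.shape
        if len(self.gene_ids) != g:
            raise DatasetFormatError(
                f"{len(self.gene_ids)} gene ids for {g} matrix rows"
            )
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DatasetFormatError(
                f"{len(self.sample_ids)} sample ids / {len(self.labels)} labels "
                f"for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != g:
            dup = _first_duplicate(self.gene_ids)
            raise DatasetFormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise DatasetFormatError(f"duplicate sample id {dup!r}")
        classes = sorted(set(self.labels))
        if len(classes) != 2:
            raise DatasetFormatError(
                f"exactly two classes required, got {len(classes)}: {classes}"
            )
        for c in classes:
            if self.labels.count(c) < 2:
                raise DatasetFormatError(
                    f"class {c!r} has fewer than 2 samples"
                )
        if not np.all(np.isfinite(self.matrix)):
            raise DatasetFormatError("expression matrix contains non-finite values")
        if self.positive_class is None:
            self.positive_class = classes[0]
        elif self.positive_class not in classes:
            raise DatasetFormatError(
                f"positive_class {self.positive_class!r} not among classes {classes}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def positive_mask(self) -> np.ndarray:
        """Boolean mask over samples selecting the positive class."""
        return np.asarray([l == self.positive_class for l in self.labels])


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate present")


def split_by_class(ds: ExpressionDataset) -> tuple[list[int], list[int]]:
    """Sample indices of the positive class and of the other class.

    Both lists preserve file (column) order; together they cover all samples.
    """
    pos = [i for i, l in enumerate(ds.labels) if l == ds.positive_class]
    neg = [i for i, l in enumerate(ds.labels) if l != ds.positive_class]
    return pos, neg


def _parse_cell(token: str, row: int, col: int, gene_id: str, sample_id: str):
    stripped = token.strip()
    if stripped.lower() in MISSING_TOKENS:
        return None
    try:
        return float(stripped)
    except ValueError:
        raise DatasetFormatError(
            f"non-numeric value {token!r} at row {row}, column {col} "
            f"(gene {gene_id!r}, sample {sample_id!r})"
        ) from None


def _read_rows(path: str | Path) -> list[list[str]]:
    # newline="" + csv handles CRLF and LF alike; blank trailing lines dropped
    with open(path, "r", newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")]
    while rows and (not rows[-1] or all(c.strip() == "" for c in rows[-1])):
        rows.pop()
    return rows


def _read_label_file(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for r, row in enumerate(_read_rows(path), start=1):
        if len(row) != 2:
            raise DatasetFormatError(
                f"label file {path}: row {r} has {len(row)} columns, expected 2"
            )
        sid, label = row[0].strip(), row[1].strip()
        if r == 1 and sid.lower() in {"sample", "sample_id", "id"}:
            continue  # tolerated header line
        if sid in mapping:
            raise DatasetFormatError(f"label file {path}: duplicate sample id {sid!r}")
        mapping[sid] = label
    return mapping


def read_dataset(
    path: str | Path,
    labels_path: str | Path | None = None,
    positive_class: str | None = None,
    impute: str | None = None,
) -> ExpressionDataset:
    """Read a two-class expression dataset from tab-delimited text.

    Parameters
    ----------
    path : path
        Matrix file in the dialect described in the module docstring.
    labels_path : path, optional
        Two-column ``sample_id<TAB>label`` file; required when the matrix
        file carries no inline ``class`` row.
    positive_class : str, optional
        Class treated as positive for direction calls; defaults to the
        lexicographically smaller label.
    impute : {None, "row-mean"}
        Missing cells are an error unless row-mean imputation is requested.
    """
    if impute not in (None, "row-mean"):
        raise ValueError(f"unknown impute mode {impute!r}")
    rows = _read_rows(path)
    if len(rows) < 2:
        raise DatasetFormatError(f"{path}: fewer than 2 rows")

    data_start = 1
    inline_labels: list[str] | None = None
    if len(rows) > 1 and rows[1] and rows[1][0].strip().lower() == "class":
        inline_labels = [c.strip() for c in rows[1][1:]]
        data_start = 2
    data_rows = rows[data_start:]
    if not data_rows:
        raise DatasetFormatError(f"{path}: no gene rows")

    width = len(data_rows[0])  # gene_id + n values
    n = width - 1
    if n < 1:
        raise DatasetFormatError(f"{path}: first gene row has no values")
    header = rows[0]
    if len(header) == width:  # corner cell present
        sample_ids = [c.strip() for c in header[1:]]
    elif len(header) == n:
        sample_ids = [c.strip() for c in header]
    else:
        raise DatasetFormatError(
            f"{path}: header has {len(header)} fields but data rows have {width}"
        )

    gene_ids: list[str] = []
    matrix = np.empty((len(data_rows), n), dtype=float)
    for i, row in enumerate(data_rows):
        file_row = data_start + 1 + i  # 1-based row in the file
        if len(row) != width:
            raise DatasetFormatError(
                f"{path}: row {file_row} has {len(row)} fields, expected {width}"
            )
        gid = row[0].strip()
        gene_ids.append(gid)
        missing: list[int] = []
        for j, tok in enumerate(row[1:]):
            val = _parse_cell(tok, file_row, j + 2, gid, sample_ids[j])
            if val is None:
                missing.append(j)
                matrix[i, j] = np.nan
            else:
                matrix[i, j] = val
        if missing:
            if impute != "row-mean":
                j = missing[0]
                raise DatasetFormatError(
                    f"missing value at row {file_row}, column {j + 2} "
                    f"(gene {gid!r}, sample {sample_ids[j]!r}); "
                    "rerun with row-mean imputation to fill it"
                )
            present = np.isfinite(matrix[i])
            if not present.any():
                raise DatasetFormatError(
                    f"gene {gid!r} (row {file_row}) has no observed values to impute from"
                )
            matrix[i, ~present] = matrix[i, present].mean()

    if inline_labels is not None:
        if len(inline_labels) != n:
            raise DatasetFormatError(
                f"{path}: class row has {len(inline_labels)} labels for {n} samples"
            )
        labels = inline_labels
    else:
        if labels_path is None:
            raise DatasetFormatError(
                f"{path}: no inline `class` row and no label file given"
            )
        mapping = _read_label_file(labels_path)
        try:
            labels = [mapping[s] for s in sample_ids]
        except KeyError as e:
            raise DatasetFormatError(
                f"label file {labels_path}: no label for sample {e.args[0]!r}"
            ) from None

    return ExpressionDataset(matrix, gene_ids, sample_ids, labels, positive_class)


def write_dataset(ds: ExpressionDataset, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a dataset in the same tab-delimited dialect (inline labels)."""
    buf = io.StringIO()
    buf.write("gene_id\t" + "\t".join(ds.sample_ids) + "\n")
    buf.write("class\t" + "\t".join(ds.labels) + "\n")
    for gid, row in zip(ds.gene_ids, ds.matrix):
        buf.write(gid + "\t" + "\t".join(fmt % v for v in row) + "\n")
    Path(path).write_text(buf.getvalue())
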