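"""Reading and writing expression matrices, labels, gene sets and result tables.

The central container is :class:`ExpressionMatrix`: a transcripts x cells
matrix of non-negative FPKM values with transcript identifiers (Ensembl
transcript id plus gene symbol), cell identifiers and a binary per-cell
label where the positive class is tumor.

Supported on-disk formats:

* dense delimited text (TSV/CSV): first column transcript id, optional
  second column gene symbol, header row of cell ids;
* MatrixMarket triplets (``.mtx``) with ``<stem>.rows.tsv`` /
  ``<stem>.cols.tsv`` sidecars;
* two-column label files mapping cell id -> tumor/normal token;
* GMT gene-set collections;
* plain one-symbol-per-line gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Label tokens accepted for the positive (tumor) class, lowercased.
POSITIVE_TOKENS = frozenset({"tumor", "tumour", "crc", "cancer", "1", "positive"})
#: Label tokens accepted for the negative (normal) class, lowercased.
NEGATIVE_TOKENS = frozenset({"normal", "0", "negative"})

#: Significant digits used for all float output; keeps files byte-stable.
FLOAT_FORMAT = "%.6g"


@dataclass
class ExpressionMatrix:
    """Transcripts x cells non-negative expression matrix with labels.

    ``labels`` is an int8 vector over the cells: 1 = positive (tumor),
    0 = negative (normal).
    """

    values: np.ndarray
    transcript_ids: list[str]
    gene_symbols: list[str]
    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == 0))

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        nt, nc = self.values.shape
        if nt != len(self.transcript_ids):
            raise ValueError(
                f"{len(self.transcript_ids)} transcript ids for {nt} rows"
            )
        if len(self.gene_symbols) != len(self.transcript_ids):
            raise ValueError("gene_symbols must parallel transcript_ids")
        if nc != len(self.cell_ids):
            raise ValueError(f"{len(self.cell_ids)} cell ids for {nc} columns")
        if len(self.labels) != nc:
            raise ValueError("labels must have one entry per cell")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            t, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at transcript "
                f"{self.transcript_ids[t]!r}, cell {self.cell_ids[c]!r}"
            )
        dup = _first_duplicate(self.transcript_ids)
        if dup is not None:
            raise ValueError(f"duplicate transcript id: {dup!r}")
        dup = _first_duplicate(self.cell_ids)
        if dup is not None:
            raise ValueError(f"duplicate cell id: {dup!r}")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be 0 (normal) or 1 (tumor)")

    def require_both_classes(self) -> None:
        """Raise unless both a positive and a negative cell are present."""
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError(
                f"both classes required: {self.n_pos} positive, "
                f"{self.n_neg} negative cells"
            )

    # -- subsetting --------------------------------------------------------
    def subset_transcripts(self, rows: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        """Row-subset (and/or reorder) by integer indices, order preserved."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return ExpressionMatrix(
            values=self.values[rows],
            transcript_ids=[self.transcript_ids[i] for i in rows],
            gene_symbols=[self.gene_symbols[i] for i in rows],
            cell_ids=list(self.cell_ids),
            labels=self.labels.copy(),
        )

    def subset_by_ids(self, ids: Sequence[str]) -> "ExpressionMatrix":
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        missing = [t for t in ids if t not in index]
        if missing:
            raise KeyError(f"unknown transcript ids: {missing[:5]}")
        return self.subset_transcripts([index[t] for t in ids])

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.cell_ids)
        df.insert(0, "gene_symbol", self.gene_symbols)
        df.insert(0, "transcript_id", self.transcript_ids)
        return df


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols are uppercased on load, duplicates dropped."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        uniq = list(dict.fromkeys(g.upper() for g in genes if g))
        if not uniq:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(name, description, uniq)


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_expression`.

    ``n_cells_dropped``: matrix columns removed because no label was given.
    ``n_labels_unmatched``: labeled cell ids absent from the matrix.
    """

    n_cells_dropped: int = 0
    n_labels_unmatched: int = 0


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_labels(
    path: str | Path,
    positive_tokens: frozenset[str] = POSITIVE_TOKENS,
    negative_tokens: frozenset[str] = NEGATIVE_TOKENS,
) -> dict[str, int]:
    """Read a two-column cell id -> class token file (no header).

    Tokens are matched case-insensitively; unknown tokens are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (cell id, label)")
    out: dict[str, int] = {}
    for _, (cell, token) in df.iloc[:, :2].iterrows():
        t = str(token).strip().lower()
        if t in positive_tokens:
            out[str(cell)] = 1
        elif t in negative_tokens:
            out[str(cell)] = 0
        else:
            raise ValueError(f"{path}: unrecognized class token {token!r} for cell {cell!r}")
    return out


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    positive_tokens: frozenset[str] = POSITIVE_TOKENS,
    negative_tokens: frozenset[str] = NEGATIVE_TOKENS,
) -> tuple[ExpressionMatrix, LoadReport]:
    """Load an expression matrix plus labels from disk.

    ``matrix_path`` may be dense delimited text or a ``.mtx`` MatrixMarket
    file (with ``<stem>.rows.tsv`` and ``<stem>.cols.tsv`` sidecars). Cells
    without a label are dropped with a warning; labeled cells missing from
    the matrix are counted in the report. Cell order follows the matrix.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix.lower() == ".mtx":
        values, transcript_ids, gene_symbols, cell_ids = _read_mtx(matrix_path)
    else:
        values, transcript_ids, gene_symbols, cell_ids = _read_dense(matrix_path)

    label_map = read_labels(
        labels_path, positive_tokens=positive_tokens, negative_tokens=negative_tokens
    )
    keep = [i for i, c in enumerate(cell_ids) if c in label_map]
    if not keep:
        raise ValueError(
            "no overlap between labeled cells and matrix columns "
            f"({matrix_path}, {labels_path})"
        )
    report = LoadReport(
        n_cells_dropped=len(cell_ids) - len(keep),
        n_labels_unmatched=len(set(label_map) - set(cell_ids)),
    )
    if report.n_cells_dropped:
        logger.warning("%d matrix cells had no label and were dropped", report.n_cells_dropped)
    if report.n_labels_unmatched:
        logger.warning("%d labeled cells were absent from the matrix", report.n_labels_unmatched)

    cell_ids = [cell_ids[i] for i in keep]
    matrix = ExpressionMatrix(
        values=values[:, keep],
        transcript_ids=transcript_ids,
        gene_symbols=gene_symbols,
        cell_ids=cell_ids,
        labels=np.array([label_map[c] for c in cell_ids], dtype=np.int8),
    )
    return matrix, report


def _read_dense(path: Path) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least a transcript id column and one cell")
    transcript_ids = df.iloc[:, 0].astype(str).tolist()
    rest = df.iloc[:, 1:]
    # The gene-symbol column is optional: present when the second column is
    # entirely non-numeric. When absent, symbols fall back to transcript ids.
    first = pd.to_numeric(rest.iloc[:, 0], errors="coerce")
    if len(rest.columns) > 1 and first.isna().all() and len(df) > 0:
        gene_symbols = rest.iloc[:, 0].astype(str).tolist()
        rest = rest.iloc[:, 1:]
    else:
        gene_symbols = list(transcript_ids)
    cell_ids = [str(c) for c in rest.columns]
    numeric = rest.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric entry at transcript {transcript_ids[r]!r}, "
            f"cell {cell_ids[c]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative entry at transcript {transcript_ids[r]!r}, "
            f"cell {cell_ids[c]!r}"
        )
    return values, transcript_ids, gene_symbols, cell_ids


def _read_mtx(path: Path) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    stem = path.with_suffix("")
    rows_path = stem.with_suffix(".rows.tsv")
    cols_path = stem.with_suffix(".cols.tsv")
    m = scipy.io.mmread(path)
    values = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
    rows = pd.read_csv(rows_path, sep="\t", header=None, dtype=str)
    transcript_ids = rows.iloc[:, 0].tolist()
    gene_symbols = rows.iloc[:, 1].tolist() if rows.shape[1] > 1 else list(transcript_ids)
    cell_ids = pd.read_csv(cols_path, sep="\t", header=None, dtype=str).iloc[:, 0].tolist()
    return values, transcript_ids, gene_symbols, cell_ids


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    """Write a dense TSV matrix (and optionally a labels TSV)."""
    matrix.to_frame().to_csv(
        Path(matrix_path), sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    if labels_path is not None:
        tokens = np.where(matrix.labels == 1, "tumor", "normal")
        pd.DataFrame({"cell": matrix.cell_ids, "label": tokens}).to_csv(
            Path(labels_path), sep="\t", index=False, header=False
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            collection.add(fields[0], fields[1], fields[2:])
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; uppercased, de-duplicated, order preserved."""
    with open(path) as fh:
        return list(dict.fromkeys(
            line.strip().upper() for line in fh if line.strip()
        ))


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_table(records, path: str | Path) -> None:
    """Write any tabular result as deterministic TSV.

    Accepts a DataFrame, a sequence of dataclasses/dicts, or a mapping of
    columns. Floats use 6 significant digits, missing values render as "NA";
    output is byte-stable for identical inputs.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records) if not isinstance(records, Mapping) else records
        if isinstance(records, Mapping):
            df = pd.DataFrame(records)
        elif records and hasattr(records[0], "__dataclass_fields__"):
            df = pd.DataFrame([vars(r) for r in records])
        else:
            df = pd.DataFrame(records)
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")
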