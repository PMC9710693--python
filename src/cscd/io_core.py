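"""Expression-matrix containers, readers/writers and pre-processing filters.

Bulk and single-cell expression are held in a common ``ExpressionMatrix``
(genes x columns, non-negative, flagged as raw counts or CPM).  The
pre-processing applied before decomposition removes genes that carry no
usable signal: zero variance across single cells, all-zero bulk rows, and
mitochondrial genes (recognised by gene-symbol prefix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

CPM_TOTAL = 1e6
COUNTS = "counts"
CPM = "cpm"

#: gene-symbol prefixes treated as mitochondrial (case-insensitive match)
DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


class ParseError(ValueError):
    """Raised when an expression file cannot be parsed."""


def _as_id_tuple(ids: Iterable, what: str) -> tuple[str, ...]:
    out = tuple(str(i) for i in ids)
    if len(set(out)) != len(out):
        dupes = pd.Index(out)[pd.Index(out).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return out


@dataclass
class ExpressionMatrix:
    """Genes x columns matrix of non-negative expression values.

    Parameters
    ----------
    values
        2-D array, genes in rows.
    gene_ids, column_ids
        Unique identifiers matching the matrix dimensions.
    scale
        ``"counts"`` for raw counts, ``"cpm"`` for counts-per-million
        derived values (columns of a freshly normalized matrix sum to 1e6;
        gene-subset views keep the flag).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    column_ids: tuple[str, ...]
    scale: str = COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x columns)")
        self.gene_ids = _as_id_tuple(self.gene_ids, "gene ids")
        self.column_ids = _as_id_tuple(self.column_ids, "column ids")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be non-negative")
        if self.scale not in (COUNTS, CPM):
            raise ValueError(f"unknown scale {self.scale!r}")

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.column_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = COUNTS) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns), scale)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-restrict to ``genes`` (which must all be present), in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(
            self.values[idx, :], tuple(genes), self.column_ids, self.scale
        )


@dataclass
class SingleCellDataset:
    """Single-cell expression with per-cell type and subject annotations."""

    expr: ExpressionMatrix
    cell_type: pd.Series  # index: cell id -> type label
    subject: pd.Series  # index: cell id -> subject label

    def __post_init__(self) -> None:
        cells = list(self.expr.column_ids)
        for name, s in (("cell_type", self.cell_type), ("subject", self.subject)):
            s = pd.Series(s)
            missing = set(cells) - set(s.index)
            if missing:
                raise ValueError(f"{name} annotation missing for cells {sorted(missing)[:5]}")
            setattr(self, name, s.reindex(cells).astype(str))
        if self.n_types < 2:
            raise ValueError("single-cell dataset must contain at least 2 cell types")
        if self.n_subjects < 1:
            raise ValueError("single-cell dataset must contain at least 1 subject")

    @property
    def cell_types(self) -> tuple[str, ...]:
        """Cell-type labels in first-appearance order (fixed downstream order)."""
        return tuple(dict.fromkeys(self.cell_type))

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.subject))

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def with_expr(self, expr: ExpressionMatrix) -> "SingleCellDataset":
        return SingleCellDataset(expr, self.cell_type, self.subject)


@dataclass
class BulkDataset:
    """Bulk expression matrix (genes x samples)."""

    expr: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.expr.n_columns < 1:
            raise ValueError("bulk dataset must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.expr.n_columns


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_expression(
    path: str | Path,
    format: str | None = None,
    *,
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x columns expression matrix from CSV/TSV/MTX.

    CSV/TSV files carry gene ids in the first column and a header row of
    column ids.  MatrixMarket files need sidecar ``genes.txt`` and
    ``barcodes.txt`` (one id per line) in the same directory unless paths
    are given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            values = df.to_numpy(dtype=float)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if df.index.duplicated().any():
            raise ValueError(
                f"duplicate gene ids in {path}: "
                f"{df.index[df.index.duplicated()].unique().tolist()[:5]}"
            )
        return ExpressionMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))
    if fmt == "mtx":
        genes_file = Path(genes_file) if genes_file else path.with_name("genes.txt")
        barcodes_file = Path(barcodes_file) if barcodes_file else path.with_name("barcodes.txt")
        for p in (genes_file, barcodes_file):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX sidecar {p}")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        genes = [ln.strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
        cols = [ln.strip() for ln in barcodes_file.read_text().splitlines() if ln.strip()]
        if len(genes) != dense.shape[0] or len(cols) != dense.shape[1]:
            raise ParseError(
                f"MTX shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cols)} barcodes)"
            )
        return ExpressionMatrix(dense, tuple(genes), tuple(cols))
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix so that :func:`read_expression` round-trips it."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        m.to_frame().to_csv(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values), precision=17)
        path.with_name("genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        path.with_name("barcodes.txt").write_text("\n".join(m.column_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a cell-annotation TSV with columns cell_id, cell_type, subject."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "cell_type", "subject"}
    if not required.issubset(df.columns):
        raise ParseError(f"annotation file {path} must have columns {sorted(required)}")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"duplicate cell ids in {path}")
    return df.set_index("cell_id")


def single_cell_from_files(
    expr_path: str | Path, annot_path: str | Path, **read_kwargs
) -> SingleCellDataset:
    expr = read_expression(expr_path, **read_kwargs)
    annot = read_annotations(annot_path)
    return SingleCellDataset(expr, annot["cell_type"], annot["subject"])


# ---------------------------------------------------------------------------
# normalization / alignment / filtering
# ---------------------------------------------------------------------------

def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each column to counts-per-million (column total 1e6).

    All-zero columns pass through unchanged with a logged warning; they carry
    no information and are tolerated because real droplet data can contain
    empty cells.
    """
    if m.scale != COUNTS:
        raise ValueError(f"cpm_normalize expects counts, got scale={m.scale!r}")
    totals = m.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "cpm_normalize: %d all-zero column(s) left unscaled (e.g. %s)",
            int(zero.sum()),
            m.column_ids[int(np.flatnonzero(zero)[0])],
        )
    safe = np.where(zero, 1.0, totals)
    return ExpressionMatrix(m.values / safe * CPM_TOTAL, m.gene_ids, m.column_ids, CPM)


def align_genes(
    sc: SingleCellDataset, bulk: BulkDataset
) -> tuple[SingleCellDataset, BulkDataset]:
    """Restrict both datasets to their common genes, in lexicographic order."""
    common = sorted(set(sc.expr.gene_ids) & set(bulk.expr.gene_ids))
    if not common:
        raise ValueError("single-cell and bulk datasets share no genes")
    return (
        sc.with_expr(sc.expr.subset_genes(common)),
        BulkDataset(bulk.expr.subset_genes(common)),
    )


def filter_genes(
    sc: SingleCellDataset,
    bulk: BulkDataset,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
) -> tuple[SingleCellDataset, BulkDataset]:
    """Drop zero-variance single-cell genes, all-zero bulk rows and mito genes.

    Expects the two gene spaces to be aligned already; gene order is
    preserved.  Mitochondrial genes are recognised by a case-insensitive
    gene-symbol prefix match.
    """
    if sc.expr.gene_ids != bulk.expr.gene_ids:
        raise ValueError("gene spaces must be aligned before filtering")
    vals = sc.expr.values
    varying = np.ptp(vals, axis=1) > 0  # exact: constant rows have zero range
    expressed = bulk.expr.values.any(axis=1)
    prefixes = tuple(p.lower() for p in mito_prefixes)
    not_mito = np.array(
        [not g.lower().startswith(prefixes) for g in sc.expr.gene_ids]
    )
    keep = varying & expressed & not_mito
    if not keep.any():
        raise ValueError("all genes removed by pre-processing filters")
    kept = [g for g, k in zip(sc.expr.gene_ids, keep) if k]
    logger.info(
        "filter_genes: %d/%d genes retained (%d zero-variance, %d unexpressed, %d mito)",
        len(kept), len(keep), int((~varying).sum()), int((~expressed).sum()),
        int((~not_mito).sum()),
    )
    return (
        sc.with_expr(sc.expr.subset_genes(kept)),
        BulkDataset(bulk.expr.subset_genes(kept)),
    )
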