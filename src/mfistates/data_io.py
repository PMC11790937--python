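"""Reading, QC, gene selection and binarisation of expression matrices.

The on-disk contracts are:

* dense CSV — header row of gene names, one row per cell (cells x genes);
* Matrix Market triplet (``.mtx``) in the 10x layout (genes x cells) with
  ``genes.tsv`` and ``barcodes.tsv`` sidecars; transposed to cells x genes
  on load.

All downstream statistics operate on the binarised matrix: an entry is 1
iff the gene shows any expression evidence (count strictly positive).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


def _check_names(names: Sequence[str], kind: str) -> list[str]:
    names = [str(n) for n in names]
    seen: dict[str, int] = {}
    for i, n in enumerate(names):
        if n in seen:
            raise ParseError(
                f"duplicated {kind} name {n!r} (columns {seen[n]} and {i})"
            )
        seen[n] = i
    return names


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of non-negative counts (or normalised values)."""

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        self.gene_names = _check_names(self.gene_names, "gene")
        self.cell_ids = _check_names(self.cell_ids, "cell")
        n_cells, n_genes = self.values.shape
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n_genes} columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cells} rows")
        if np.any(self.values < 0):
            raise ValueError("negative entries are not valid expression counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass
class BinaryMatrix(ExpressionMatrix):
    """Cells x genes matrix with entries in {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("BinaryMatrix entries must all be 0 or 1")
        self.values = self.values.astype(np.int8)


def load_expression(path: str, format: str = "csv") -> ExpressionMatrix:
    """Load an expression matrix from ``csv`` or 10x-style ``mtx``.

    CSV files are read as cells x genes with the first row holding gene
    names; ``.mtx`` files are read genes x cells (10x convention) together
    with ``genes.tsv``/``barcodes.tsv`` sidecars in the same directory, and
    transposed so the returned matrix is always cells x genes.
    """
    if format == "csv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        # pandas silently renames duplicate columns, so validate first
        genes = _check_names([t.strip() for t in header.split(",")], "gene")
        try:
            df = pd.read_csv(path, header=0)
        except Exception as exc:  # malformed csv
            raise ParseError(f"could not parse {path}: {exc}") from exc
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[
                [not np.issubdtype(t, np.number) for t in df.dtypes]
            ].tolist()
            raise ParseError(f"non-numeric entries in columns {bad}")
        cells = [f"cell_{i}" for i in range(values.shape[0])]
        return ExpressionMatrix(values=values, gene_names=genes, cell_ids=cells)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"could not parse {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float).T  # stored genes x cells
        base = os.path.dirname(path)
        genes_path = os.path.join(base, "genes.tsv")
        barcodes_path = os.path.join(base, "barcodes.tsv")
        genes = _read_sidecar(genes_path, "genes")
        cells = _read_sidecar(barcodes_path, "barcodes")
        if len(genes) != mat.shape[1]:
            raise ParseError(
                f"{genes_path}: {len(genes)} genes but matrix has "
                f"{mat.shape[1]} gene rows"
            )
        if len(cells) != mat.shape[0]:
            raise ParseError(
                f"{barcodes_path}: {len(cells)} barcodes but matrix has "
                f"{mat.shape[0]} cell columns"
            )
        return ExpressionMatrix(values=mat, gene_names=genes, cell_ids=cells)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'mtx'")


def _read_sidecar(path: str, kind: str) -> list[str]:
    if not os.path.exists(path):
        raise ParseError(f"missing {kind} sidecar file {path}")
    with open(path) as fh:
        # 10x genes.tsv may carry two columns (id, symbol); take the first.
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_csv(m: ExpressionMatrix, path: str) -> None:
    """Write a cells x genes CSV that `load_expression` reads back bit-exactly."""
    df = pd.DataFrame(m.values, columns=m.gene_names)
    df.to_csv(path, index=False)


def write_mtx(m: ExpressionMatrix, path: str) -> None:
    """Write the 10x triplet layout (genes x cells + sidecars)."""
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values.T))
    base = os.path.dirname(path)
    with open(os.path.join(base, "genes.tsv"), "w") as fh:
        fh.writelines(f"{g}\n" for g in m.gene_names)
    with open(os.path.join(base, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{c}\n" for c in m.cell_ids)


def apply_qc(
    m: ExpressionMatrix,
    exclude: Optional[Sequence[bool]] = None,
    min_counts: int = 0,
    max_mito_frac: Optional[float] = None,
    mito_prefix: str = "mt-",
) -> ExpressionMatrix:
    """Remove excluded / low-quality cells; the gene set is unchanged.

    Defaults are "agnostic": with no arguments the matrix passes through
    untouched (the data are assumed pre-QCed); `exclude` is an explicit
    per-cell boolean drop list (e.g. a doublet annotation); `min_counts`
    and `max_mito_frac` switch on basic scRNA-seq QC, with mitochondrial
    genes identified by a case-insensitive name prefix.
    """
    keep = np.ones(m.n_cells, dtype=bool)
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != (m.n_cells,):
            raise ValueError(
                f"exclusion list has length {exclude.size}, expected {m.n_cells}"
            )
        keep &= ~exclude
    totals = m.values.sum(axis=1)
    if min_counts > 0:
        keep &= totals >= min_counts
    if max_mito_frac is not None:
        is_mito = np.array(
            [g.lower().startswith(mito_prefix.lower()) for g in m.gene_names]
        )
        mito_counts = m.values[:, is_mito].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        keep &= frac <= max_mito_frac
    return ExpressionMatrix(
        values=m.values[keep],
        gene_names=list(m.gene_names),
        cell_ids=[c for c, k in zip(m.cell_ids, keep) if k],
    )


def hvg_statistic(m: ExpressionMatrix, scale: float = 1e4) -> np.ndarray:
    """Per-gene variability: variance of log1p(counts scaled to `scale` per cell).

    Cells with zero total count contribute zeros (they carry no evidence
    either way).
    """
    totals = m.values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, m.values / totals * scale, 0.0)
    return np.log1p(norm).var(axis=0)


def select_genes(
    m: ExpressionMatrix,
    n_genes: int,
    user_genes: Optional[Sequence[str]] = None,
) -> ExpressionMatrix:
    """Keep `n_genes` columns: user genes first, then the most variable.

    User genes are retained regardless of their variability, in the order
    given; the remaining slots are filled with the highest `hvg_statistic`
    genes, ties broken by input column order.
    """
    user_genes = list(user_genes or [])
    unknown = [g for g in user_genes if g not in m.gene_names]
    if unknown:
        raise KeyError(f"user genes not in matrix: {unknown}")
    if n_genes < len(user_genes):
        raise ValueError(
            f"n_genes={n_genes} smaller than the {len(user_genes)} user genes"
        )
    n_genes = min(n_genes, m.n_genes)
    stat = hvg_statistic(m)
    user_idx = [m.gene_names.index(g) for g in user_genes]
    taken = set(user_idx)
    # stable sort: descending variability, ties by column order
    order = sorted(range(m.n_genes), key=lambda i: (-stat[i], i))
    fill = [i for i in order if i not in taken][: n_genes - len(user_idx)]
    cols = user_idx + fill
    return ExpressionMatrix(
        values=m.values[:, cols],
        gene_names=[m.gene_names[i] for i in cols],
        cell_ids=list(m.cell_ids),
    )


def binarise(m: ExpressionMatrix) -> BinaryMatrix:
    """Map strictly positive evidence to 1, absence of evidence to 0."""
    return BinaryMatrix(
        values=(m.values > 0).astype(np.int8),
        gene_names=list(m.gene_names),
        cell_ids=list(m.cell_ids),
    )
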