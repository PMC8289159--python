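"""Expression matrix container, MatrixMarket I/O, quality filtering and normalization.

The central object is :class:`ExpressionMatrix`: a sparse gene x cell count
matrix with ordered gene/cell identifiers and a lazily attached log-normalized
layer.  Genes are rows and cells are columns throughout (full-length scRNA-seq
convention for per-gene genomic operations downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import EmptyAfterQCError, FormatError, InvariantError

DEFAULT_SCALE = 100_000  # counts per hundred thousand
DEFAULT_MITO_PREFIX = "MT-"


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell counts plus an optional log-normalized dense layer.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes as rows, cells as columns.
    gene_ids, cell_ids
        Unique ordered identifiers for rows and columns.
    lognorm
        ``log(1 + scale * count / cell_total)`` dense array, set by
        :func:`normalize`; ``None`` until then.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    lognorm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, idx in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if idx.has_duplicates:
                dup = idx[idx.duplicated()][0]
                raise FormatError(f"duplicate {name} id: {dup!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative entries in count matrix")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def require_lognorm(self) -> np.ndarray:
        if self.lognorm is None:
            raise InvariantError("normalized layer missing; call normalize() first")
        return self.lognorm

    def subset(self, genes: Sequence[str] | None = None,
               cells: Sequence[str] | None = None) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given genes/cells (order kept)."""
        gi = (self.gene_ids.get_indexer(pd.Index(genes)) if genes is not None
              else np.arange(self.n_genes))
        ci = (self.cell_ids.get_indexer(pd.Index(cells)) if cells is not None
              else np.arange(self.n_cells))
        if genes is not None and (gi < 0).any():
            missing = pd.Index(genes)[gi < 0][0]
            raise KeyError(f"unknown gene id: {missing!r}")
        if cells is not None and (ci < 0).any():
            missing = pd.Index(cells)[ci < 0][0]
            raise KeyError(f"unknown cell id: {missing!r}")
        sub = ExpressionMatrix(
            counts=self.counts[gi][:, ci],
            gene_ids=self.gene_ids[gi],
            cell_ids=self.cell_ids[ci],
        )
        if self.lognorm is not None:
            sub.lognorm = self.lognorm[np.ix_(gi, ci)]
        return sub

    def lognorm_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.require_lognorm(), index=self.gene_ids,
                            columns=self.cell_ids)


@dataclass
class QCThresholds:
    """Cell/gene quality thresholds (all criteria applied jointly)."""

    min_genes_per_cell: int = 1000
    min_counts_per_cell: int = 10_000
    max_mito_fraction: float = 0.2
    min_cells_per_gene: int = 3
    mito_prefix: str = DEFAULT_MITO_PREFIX

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_counts_per_cell,
               self.min_cells_per_gene) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-criterion removal counts recorded by :func:`qc_filter`."""

    n_cells_in: int
    n_genes_in: int
    cells_failed_min_genes: int
    cells_failed_min_counts: int
    cells_failed_mito: int
    cells_removed: int
    genes_removed: int
    n_cells_out: int
    n_genes_out: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.__dict__), "value": list(self.__dict__.values())}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MatrixMarket triplet I/O
# ---------------------------------------------------------------------------

def read_matrix(mtx_path: str | Path, genes_path: str | Path,
                cells_path: str | Path) -> ExpressionMatrix:
    """Read an MTX triplet (matrix + gene TSV + cell TSV) into an ExpressionMatrix.

    Gene/cell files are single-column (or first-column) TSVs without header;
    row/column order is preserved from the files.
    """
    for p in (mtx_path, genes_path, cells_path):
        if not Path(p).exists():
            raise FormatError(f"input file not found: {p}")
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str)
    cells = pd.read_csv(cells_path, sep="\t", header=None).iloc[:, 0].astype(str)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape} but sidecars list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    return ExpressionMatrix(mat, pd.Index(genes), pd.Index(cells))


def write_matrix(matrix: ExpressionMatrix, out_dir: str | Path,
                 prefix: str = "") -> None:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / f"{prefix}matrix.mtx"), sp.coo_matrix(matrix.counts))
    matrix.gene_ids.to_series().to_csv(out / f"{prefix}genes.tsv", sep="\t",
                                       header=False, index=False)
    matrix.cell_ids.to_series().to_csv(out / f"{prefix}barcodes.tsv", sep="\t",
                                       header=False, index=False)


# ---------------------------------------------------------------------------
# Quality filtering and normalization
# ---------------------------------------------------------------------------

def qc_filter(matrix: ExpressionMatrix,
              thresholds: QCThresholds | None = None
              ) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells, then genes detected in too few surviving cells.

    Cells failing any cell-level criterion (detected genes, total counts,
    mitochondrial fraction) are removed first; genes detected in fewer than
    ``min_cells_per_gene`` of the surviving cells are removed second.
    """
    th = thresholds or QCThresholds()
    counts = matrix.counts
    detected = counts.astype(bool)
    genes_per_cell = np.asarray(detected.sum(axis=0)).ravel()
    counts_per_cell = np.asarray(counts.sum(axis=0)).ravel()
    mito_mask = matrix.gene_ids.str.startswith(th.mito_prefix)
    if mito_mask.any():
        mito_counts = np.asarray(counts[np.where(mito_mask)[0]].sum(axis=0)).ravel()
    else:
        mito_counts = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(counts_per_cell > 0, mito_counts / np.maximum(counts_per_cell, 1), 0.0)

    fail_genes = genes_per_cell < th.min_genes_per_cell
    fail_counts = counts_per_cell < th.min_counts_per_cell
    fail_mito = mito_frac > th.max_mito_fraction
    keep_cells = ~(fail_genes | fail_counts | fail_mito)
    if not keep_cells.any():
        raise EmptyAfterQCError("empty after QC: every cell failed a cell-level criterion")

    kept = matrix.subset(cells=matrix.cell_ids[keep_cells])
    cells_per_gene = np.asarray(kept.counts.astype(bool).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= th.min_cells_per_gene
    out = kept.subset(genes=kept.gene_ids[keep_genes])

    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_genes_in=matrix.n_genes,
        cells_failed_min_genes=int(fail_genes.sum()),
        cells_failed_min_counts=int(fail_counts.sum()),
        cells_failed_mito=int(fail_mito.sum()),
        cells_removed=int((~keep_cells).sum()),
        genes_removed=int((~keep_genes).sum()),
        n_cells_out=out.n_cells,
        n_genes_out=out.n_genes,
    )
    return out, report


def normalize(matrix: ExpressionMatrix, scale: int = DEFAULT_SCALE) -> ExpressionMatrix:
    """Attach the log-normalized layer: log(1 + scale * count / cell_total).

    Returns the same object with ``lognorm`` set.  A zero-total cell is an
    invariant violation (QC removes such cells when ``min_counts_per_cell >= 1``).
    """
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = matrix.cell_ids[totals == 0][0]
        raise InvariantError(f"zero-total cell encountered during normalize: {bad!r}")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    matrix.lognorm = np.log1p(scale * dense / totals[None, :])
    return matrix
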