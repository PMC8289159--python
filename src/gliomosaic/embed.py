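"""Bulk-CNV-informed gene masking, variable-gene selection, embedding, clustering.

Malignant cells from different patients fragment in a naive embedding because
copy-number dosage shifts the expression of whole genomic regions in a
patient-specific way.  The remedy implemented here removes genes lying in
genomic regions whose bulk copy number is abnormal in three or more patients
(the "stable-region mask": a gene is retained iff its copy stays strictly
inside (low, high) in all but at most ``max_abnormal_patients`` patients),
then selects highly variable genes, runs PCA, builds a kNN graph, clusters by
Leiden community detection, and lays out a t-SNE for visualization only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, FormatError
from .io_qc import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class BulkCopyNumberProfile:
    """Per-sample genomic segments with estimated copy number (0-based half-open)."""

    sample: str
    segments: pd.DataFrame  # columns: chrom, start, end, copy
    patient: str | None = None

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "copy"}
        if not need.issubset(self.segments.columns):
            raise FormatError(f"segments need columns {sorted(need)}")
        if (self.segments["copy"] <= 0).any():
            raise FormatError(f"sample {self.sample}: non-positive copy number")
        for chrom, block in self.segments.groupby("chrom"):
            b = block.sort_values("start")
            if (b["end"].values[:-1] > b["start"].values[1:]).any():
                raise FormatError(
                    f"sample {self.sample}: overlapping segments on {chrom}")
        if self.patient is None:
            self.patient = self.sample


def read_segments(path: str | Path) -> list[BulkCopyNumberProfile]:
    """Read a SEG-like TSV: sample, chrom, start, end, copy[, patient]."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for sample, block in df.groupby("sample", sort=False):
        patient = block["patient"].iloc[0] if "patient" in block.columns else None
        profiles.append(BulkCopyNumberProfile(
            sample=str(sample),
            segments=block[["chrom", "start", "end", "copy"]].reset_index(drop=True),
            patient=None if patient is None else str(patient)))
    return profiles


def write_segments(profiles: Iterable[BulkCopyNumberProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        seg = p.segments.copy()
        seg.insert(0, "sample", p.sample)
        seg["patient"] = p.patient
        rows.append(seg)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


@dataclass
class MaskParams:
    """Stable-region criterion: abnormal when copy <= low or >= high (the
    interval (low, high) is open); a gene is retained when abnormal in at most
    max_abnormal_patients patients."""

    low: float = 1.8
    high: float = 2.2
    max_abnormal_patients: int = 2

    def __post_init__(self) -> None:
        if not self.low < 2 < self.high:
            raise ConfigurationError("need low < 2 < high")


@dataclass
class EmbedParams:
    n_hvg: int = 2000
    n_pcs: int = 30
    knn: int = 15
    resolution: float = 1.0
    perplexity: float = 30.0
    seed: int = 0


def _gene_copy_in_sample(annotation: pd.DataFrame,
                         profile: BulkCopyNumberProfile) -> pd.Series:
    """Copy number of each gene in one sample; uncovered positions are 2.0.

    A gene straddling two adjacent segments takes the segment with the larger
    overlap.
    """
    copies = pd.Series(2.0, index=annotation.index)
    for chrom, seg in profile.segments.groupby("chrom"):
        genes = annotation[annotation["chrom"] == chrom]
        if genes.empty:
            continue
        seg = seg.sort_values("start")
        s_start = seg["start"].values
        s_end = seg["end"].values
        s_copy = seg["copy"].values
        g_start = genes["start"].values
        g_end = genes["end"].values
        best_overlap = np.zeros(len(genes))
        best_copy = np.full(len(genes), 2.0)
        for a, b, c in zip(s_start, s_end, s_copy):
            ov = np.minimum(g_end, b) - np.maximum(g_start, a)
            take = ov > best_overlap
            best_copy[take] = c
            best_overlap[take] = ov[take]
        copies.loc[genes.index] = best_copy
    return copies


def gene_copy_table(profiles: Sequence[BulkCopyNumberProfile],
                    annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample matrix of bulk copy numbers."""
    return pd.DataFrame(
        {p.sample: _gene_copy_in_sample(annotation, p) for p in profiles})


def stable_region_mask(profiles: Sequence[BulkCopyNumberProfile],
                       annotation: pd.DataFrame,
                       params: MaskParams | None = None) -> pd.Series:
    """Per-gene boolean mask (True = retained for clustering).

    A gene is abnormal in a patient when any of the patient's samples places
    it on a segment with copy <= low or >= high; it is retained when the
    number of abnormal patients does not exceed max_abnormal_patients.
    """
    params = params or MaskParams()
    copies = gene_copy_table(profiles, annotation)
    abnormal = (copies <= params.low) | (copies >= params.high)
    patients = pd.Series({p.sample: p.patient for p in profiles})
    abnormal_patients = abnormal.T.groupby(patients).any().T.sum(axis=1)
    mask = abnormal_patients <= params.max_abnormal_patients
    mask.name = "retained"
    return mask


def write_mask(mask: pd.Series, path: str | Path) -> None:
    mask.rename("retained").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variable genes, embedding, clustering
# ---------------------------------------------------------------------------

def _to_adata(matrix: ExpressionMatrix, genes: Sequence[str] | None = None) -> ad.AnnData:
    lognorm = matrix.require_lognorm()
    if genes is not None:
        rows = matrix.gene_ids.get_indexer(pd.Index(genes))
        lognorm = lognorm[rows]
        var = pd.DataFrame(index=pd.Index(genes))
    else:
        var = pd.DataFrame(index=matrix.gene_ids)
    return ad.AnnData(X=np.ascontiguousarray(lognorm.T),
                      obs=pd.DataFrame(index=matrix.cell_ids), var=var)


def select_hvg(matrix: ExpressionMatrix, mask: pd.Series | None,
               n_hvg: int = 2000) -> list[str]:
    """Top dispersion-ranked variable genes among the mask-retained genes."""
    if mask is None:
        retained = matrix.gene_ids
    else:
        retained = matrix.gene_ids[mask.reindex(matrix.gene_ids, fill_value=False).values]
    if len(retained) == 0:
        raise ConfigurationError("mask retains no genes")
    if len(retained) <= n_hvg:
        if len(retained) < n_hvg:
            log.warning("only %d retained genes (< n_hvg=%d); using all",
                        len(retained), n_hvg)
        return list(retained)
    adata = _to_adata(matrix, retained)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_hvg)
    return list(adata.var_names[adata.var["highly_variable"]])


def embed_and_cluster(matrix: ExpressionMatrix, genes: Sequence[str],
                      params: EmbedParams | None = None,
                      compute_tsne: bool = True
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """PCA -> kNN graph -> Leiden clusters; t-SNE from the same PCs for display.

    Clusters are derived from the graph, never from 2-D coordinates.
    Returns (coords with columns tsne1/tsne2, labels).
    """
    params = params or EmbedParams()
    if matrix.n_cells < params.knn + 1:
        raise ConfigurationError(
            f"need >= knn+1={params.knn + 1} cells, got {matrix.n_cells}")
    n_pcs = params.n_pcs
    if n_pcs >= min(matrix.n_cells, len(genes)):
        raise ConfigurationError(
            f"n_pcs={n_pcs} must be < min(cells, genes)="
            f"{min(matrix.n_cells, len(genes))}")
    adata = _to_adata(matrix, genes)
    sc.pp.scale(adata, max_value=10)
    sc.tl.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=params.seed)
    sc.pp.neighbors(adata, n_neighbors=params.knn, n_pcs=n_pcs,
                    random_state=params.seed)
    sc.tl.leiden(adata, resolution=params.resolution, random_state=params.seed,
                 flavor="leidenalg", n_iterations=2)
    labels = pd.Series(adata.obs["leiden"].astype(int).values + 1,
                       index=matrix.cell_ids, name="cluster")
    if compute_tsne:
        sc.tl.tsne(adata, n_pcs=n_pcs, perplexity=min(params.perplexity,
                                                      (matrix.n_cells - 1) / 3),
                   random_state=params.seed, n_jobs=1)
        coords = pd.DataFrame(adata.obsm["X_tsne"], index=matrix.cell_ids,
                              columns=["tsne1", "tsne2"])
    else:
        coords = pd.DataFrame(adata.obsm["X_pca"][:, :2], index=matrix.cell_ids,
                              columns=["pc1", "pc2"])
    return coords, labels


def pca_coordinates(matrix: ExpressionMatrix, genes: Sequence[str],
                    params: EmbedParams) -> np.ndarray:
    adata = _to_adata(matrix, genes)
    sc.pp.scale(adata, max_value=10)
    n_pcs = min(params.n_pcs, min(adata.shape) - 1)
    sc.tl.pca(adata, n_comps=n_pcs, svd_solver="arpack", random_state=params.seed)
    return adata.obsm["X_pca"]


def _knn_patient_entropy(pcs: np.ndarray, types: pd.Series, patients: pd.Series,
                        knn: int) -> float:
    """Mean per-cell entropy of patient labels among same-type kNN neighbors,
    normalized per type by log(#patients carrying that type)."""
    entropies: list[float] = []
    for t in pd.unique(types):
        sel = np.where(types.values == t)[0]
        pats = pd.unique(patients.values[sel])
        if len(pats) < 2 or len(sel) < 3:
            continue
        k = min(knn, len(sel) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs[sel])
        _, idx = nn.kneighbors(pcs[sel])
        neigh_pat = patients.values[sel][idx[:, 1:]]
        pat_codes = pd.Categorical(neigh_pat.ravel(), categories=pats).codes
        pat_codes = pat_codes.reshape(neigh_pat.shape)
        norm = np.log(len(pats))
        for row in pat_codes:
            counts = np.bincount(row, minlength=len(pats)).astype(float)
            p = counts / counts.sum()
            p = p[p > 0]
            entropies.append(float(-(p * np.log(p)).sum() / norm))
    if not entropies:
        raise ConfigurationError("no cell type is shared by >= 2 patients")
    return float(np.mean(entropies))


def mixing_improvement(matrix: ExpressionMatrix, annotation_table: pd.DataFrame,
                       mask: pd.Series, params: EmbedParams | None = None,
                       type_col: str = "cell_type", patient_col: str = "patient"
                       ) -> tuple[float, float]:
    """Patient-mixing kNN entropy of the masked vs unmasked embedding.

    Higher is better mixed.  Returns (score_masked, score_unmasked); the
    stable-region mask should raise the score when patient-specific CNV dose
    effects are the confounder.
    """
    params = params or EmbedParams()
    ann = annotation_table.set_index("cell_id") if "cell_id" in annotation_table.columns \
        else annotation_table
    ann = ann.loc[matrix.cell_ids]
    patients = ann[patient_col]
    if patients.nunique() < 2:
        raise ConfigurationError("patient-mixing entropy undefined for one patient")
    types = ann[type_col]

    genes_masked = select_hvg(matrix, mask, params.n_hvg)
    genes_unmasked = select_hvg(matrix, None, params.n_hvg)
    pcs_masked = pca_coordinates(matrix, genes_masked, params)
    pcs_unmasked = pca_coordinates(matrix, genes_unmasked, params)
    score_masked = _knn_patient_entropy(pcs_masked, types, patients, params.knn)
    score_unmasked = _knn_patient_entropy(pcs_unmasked, types, patients, params.knn)
    return score_masked, score_unmasked
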