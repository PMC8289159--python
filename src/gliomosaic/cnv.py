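"""Expression-inferred copy-number profiles, arm summaries, CNV subgrouping,
malignancy calls.

The inference follows the moving-average approach used throughout the glioma
single-cell literature: per gene, subtract the mean log-normalized expression
of a diploid reference cell set; smooth the residual along the genome with a
centered moving average that never crosses a chromosome-arm boundary
(centromeres delimit the smoothing blocks because arm-level events are the
unit of the downstream clonal analysis); re-center each cell by its median
score; clip extremes.  Arm scores are means of the smoothed profile per arm
and approximate log-fold dosage, i.e. they increase with log2(copy/2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, InvariantError
from .genome import arm_key, genome_order, validate_annotation
from .io_qc import ExpressionMatrix

log = logging.getLogger(__name__)

REFERENCE_GATE_GENES = ("PTPRC", "MOG")  # immune / normal glia, lognorm-only gate


@dataclass
class CNVParams:
    """Tunables of the CNV inference.

    window is the moving-average span in genes (odd); gene_clip caps the
    per-gene relative log-expression before smoothing (suppresses single
    cell-type marker genes without touching dose-level shifts); clip bounds
    the final smoothed |score|; amp/del thresholds act on mean arm scores
    when discretizing events.
    """

    window: int = 101
    clip: float = 0.5
    gene_clip: float = 1.5
    reference_cells: Sequence[str] | str = "auto"
    n_subgroups: int | str = "auto"
    amp_threshold: float = 0.1
    del_threshold: float = -0.1

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError(f"window must be odd and >= 1, got {self.window}")
        if self.clip <= 0 or self.gene_clip <= 0:
            raise ConfigurationError("clip bounds must be positive")
        if not (self.amp_threshold > 0 > self.del_threshold):
            raise ConfigurationError("need amp_threshold > 0 > del_threshold")


@dataclass
class CNVMatrix:
    """Smoothed relative-expression scores, cells x genome-ordered genes."""

    score: pd.DataFrame  # index: cell ids, columns: gene ids in genome order
    clip: float

    @property
    def cell_ids(self) -> pd.Index:
        return self.score.index

    @property
    def gene_order(self) -> pd.Index:
        return self.score.columns


@dataclass
class ArmCNVMatrix:
    """Per-cell mean smoothed score per chromosome arm (genome arm order)."""

    arm_score: pd.DataFrame  # index: cell ids, columns: arm ids

    @property
    def arms(self) -> pd.Index:
        return self.arm_score.columns


def resolve_reference_cells(matrix: ExpressionMatrix,
                            gate_genes: Sequence[str] = REFERENCE_GATE_GENES,
                            detection_threshold: float = 0.0) -> pd.Index:
    """Provisional reference set: cells detecting an immune or glial marker.

    Runs on the normalized layer only, before any CNV output exists, so the
    reference choice cannot depend circularly on the CNV calls it anchors.
    """
    lognorm = matrix.require_lognorm()
    present = [g for g in gate_genes if g in matrix.gene_ids]
    if not present:
        raise ConfigurationError(
            f"none of the reference gate genes {tuple(gate_genes)} are in the matrix")
    rows = matrix.gene_ids.get_indexer(present)
    detected = (lognorm[rows] > detection_threshold).any(axis=0)
    ref = matrix.cell_ids[detected]
    if len(ref) == 0:
        raise ConfigurationError("auto reference selection found no reference cells")
    return ref


def _smooth_block(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, truncated at the block ends."""
    n = block.shape[1]
    w = min(window, n if n % 2 == 1 else n - 1)
    w = max(w, 1)
    half = w // 2
    cs = np.cumsum(block, axis=1)
    cs = np.concatenate([np.zeros((block.shape[0], 1)), cs], axis=1)
    j = np.arange(n)
    lo = np.maximum(j - half, 0)
    hi = np.minimum(j + half, n - 1)
    sums = cs[:, hi + 1] - cs[:, lo]
    return sums / (hi - lo + 1)[None, :]


def infer_cnv(matrix: ExpressionMatrix, annotation: pd.DataFrame,
              params: CNVParams | None = None) -> CNVMatrix:
    """Infer smoothed relative copy-number scores from normalized expression.

    Steps: genome-order the shared genes; subtract the reference mean per
    gene; cap the per-gene log-ratio at +/- params.gene_clip (so a single
    highly cell-type-specific gene cannot masquerade as a copy-number event);
    moving-average smooth within each chromosome arm; subtract each cell's
    median score; clip to +/- params.clip.
    """
    params = params or CNVParams()
    validate_annotation(annotation)
    lognorm = matrix.require_lognorm()

    shared = genome_order(annotation.loc[annotation.index.intersection(matrix.gene_ids)])
    if len(shared) == 0:
        raise ConfigurationError("no genes shared between matrix and annotation")
    rows = matrix.gene_ids.get_indexer(shared)
    expr = lognorm[rows].T  # cells x genes, genome order

    if isinstance(params.reference_cells, str) and params.reference_cells == "auto":
        ref_ids = resolve_reference_cells(matrix)
    else:
        ref_ids = pd.Index(params.reference_cells)
        if len(ref_ids) == 0:
            raise ConfigurationError("empty reference cell set")
        missing = ref_ids.difference(matrix.cell_ids)
        if len(missing):
            raise ConfigurationError(f"reference cells not in matrix: {list(missing[:3])}")
    ref_rows = matrix.cell_ids.get_indexer(ref_ids)
    ref_mean = expr[ref_rows].mean(axis=0)

    rel = expr - ref_mean[None, :]
    np.clip(rel, -params.gene_clip, params.gene_clip, out=rel)

    ann = annotation.loc[shared]
    blocks = pd.Index([arm_key(c, a) for c, a in zip(ann["chrom"], ann["arm"])])
    smoothed = np.empty_like(rel)
    for aid in pd.unique(blocks):
        cols = np.where(blocks == aid)[0]
        smoothed[:, cols] = _smooth_block(rel[:, cols], params.window)

    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    np.clip(smoothed, -params.clip, params.clip, out=smoothed)
    return CNVMatrix(
        score=pd.DataFrame(smoothed, index=matrix.cell_ids, columns=shared),
        clip=params.clip,
    )


def summarize_arms(cnv: CNVMatrix, annotation: pd.DataFrame,
                   min_genes_per_arm: int = 25) -> ArmCNVMatrix:
    """Mean smoothed score per cell per chromosome arm.

    Arms with fewer than ``min_genes_per_arm`` scored genes are dropped with
    a warning: a handful of genes cannot support an arm-level call and such
    arms otherwise dominate the per-cell noise (their selected fluctuations
    masquerade as subclonal events).
    """
    ann = annotation.loc[cnv.gene_order]
    arms = pd.Index([arm_key(c, a) for c, a in zip(ann["chrom"], ann["arm"])])
    cols = {}
    for aid in pd.unique(arms):
        idx = np.where(arms == aid)[0]
        if len(idx) < min_genes_per_arm:
            log.warning("arm %s has %d genes (< %d); dropped from arm summary",
                        aid, len(idx), min_genes_per_arm)
            continue
        cols[aid] = cnv.score.values[:, idx].mean(axis=1)
    if not cols:
        raise InvariantError("no arm has enough genes for an arm-level summary")
    return ArmCNVMatrix(arm_score=pd.DataFrame(cols, index=cnv.cell_ids))


def cluster_cnv_subgroups(arm: ArmCNVMatrix,
                          params: CNVParams | None = None) -> pd.Series:
    """Hierarchical (Ward/Euclidean) clustering of arm scores into CNV subgroups.

    ``n_subgroups="auto"`` picks k in [2, 8] maximizing mean silhouette.
    Returns integer labels 1..k (label ``1`` is arbitrary; identity is defined
    by membership).  All-identical input degenerates to a single cluster.
    """
    params = params or CNVParams()
    X = arm.arm_score.values
    n = X.shape[0]
    if n < 2:
        raise ConfigurationError("need >= 2 cells to cluster CNV subgroups")
    if np.allclose(X, X[0][None, :]):
        log.warning("all arm profiles identical; returning a single degenerate cluster")
        return pd.Series(1, index=arm.arm_score.index, name="cnv_subgroup")
    link = sch.linkage(X, method="ward", metric="euclidean")
    k = params.n_subgroups
    if isinstance(k, str) and k == "auto":
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(8, n - 1) + 1):
            lab = sch.fcluster(link, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(X, lab)
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    if k > n:
        raise ConfigurationError(f"n_subgroups={k} exceeds cell count {n}")
    labels = sch.fcluster(link, k, criterion="maxclust")
    return pd.Series(labels, index=arm.arm_score.index, name="cnv_subgroup")


def call_malignant(arm: ArmCNVMatrix, labels: pd.Series,
                   amp_threshold: float = 0.1) -> pd.Series:
    """Per-cell malignancy: a subgroup without an obvious CNV on any arm is
    non-malignant; cells inherit their subgroup's call.

    "Obvious CNV" means the subgroup's mean arm score reaches amp_threshold
    in magnitude on at least one arm.
    """
    labels = labels.reindex(arm.arm_score.index)
    flags = pd.Series(False, index=arm.arm_score.index, name="malignant")
    for lab in pd.unique(labels):
        members = labels.index[labels == lab]
        group_mean = arm.arm_score.loc[members].mean(axis=0)
        flags.loc[members] = bool((group_mean.abs() >= amp_threshold).any())
    return flags
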