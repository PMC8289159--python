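"""Cell typing by ordered marker gates and TCGA GBM subtype classification.

Gates implement the marker logic used for glioma cohorts: a cell takes the
label of the first gate whose conditions all hold — a required marker set
(any one detected suffices), a forbidden marker set (none detected) and a
malignancy requirement checked against the CNV call.  MKI67 detection sets
an independent "proliferating" flag rather than a label.  Malignant cells
are additionally classified into TCGA GBM expression subtypes (proneural,
classical, mesenchymal, neural) by signature averaging of z-scored
log-expression; the argmax signature wins, ties are reported as "ambiguous".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_qc import ExpressionMatrix

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"
PROLIFERATION_MARKER = "MKI67"


@dataclass(frozen=True)
class MarkerGate:
    label: str
    markers_any: tuple[str, ...]            # >= 1 must be detected
    forbidden: tuple[str, ...] = ()         # none may be detected
    requires_malignant: str = "any"         # "yes" | "no" | "any"


@dataclass
class MarkerGateConfig:
    gates: list[MarkerGate]
    detection_threshold: float = 0.0
    proliferation_marker: str = PROLIFERATION_MARKER

    def __post_init__(self) -> None:
        labels = [g.label for g in self.gates]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("gate labels must be unique")
        if self.detection_threshold < 0:
            raise ConfigurationError("detection_threshold must be >= 0")


def default_gates() -> MarkerGateConfig:
    """Coarse gate order: metastasis, immune, normal glia, ciliated tumor, glioma."""
    return MarkerGateConfig(gates=[
        MarkerGate("metastasis", ("KRT5",), requires_malignant="yes"),
        MarkerGate("immune", ("PTPRC",), requires_malignant="no"),
        MarkerGate("normal glia", ("MOG",), forbidden=("PTPRC",), requires_malignant="no"),
        MarkerGate("ciliated tumor", ("HYDIN",), requires_malignant="yes"),
        MarkerGate("glioma", ("PTPRZ1", "OLIG2", "AQP4"), requires_malignant="yes"),
    ])


def extended_gates() -> MarkerGateConfig:
    """Gate order with fine immune types resolved before the coarse immune gate;
    used by the pipeline so the cross-talk map can distinguish microglia,
    macrophages, M2b cells, lymphocytes and neutrophils."""
    fine = [
        MarkerGate("metastasis", ("KRT5",), requires_malignant="yes"),
        MarkerGate("M2b", ("IL1RN",), requires_malignant="no"),
        MarkerGate("microglia", ("P2RY12", "TMEM119"), requires_malignant="no"),
        MarkerGate("macrophage", ("CD163",), requires_malignant="no"),
        MarkerGate("lymphocyte", ("CD2", "CD3D"), requires_malignant="no"),
        MarkerGate("neutrophil", ("FCGR3B", "CSF3R"), requires_malignant="no"),
        MarkerGate("immune", ("PTPRC",), requires_malignant="no"),
        MarkerGate("normal glia", ("MOG",), forbidden=("PTPRC",), requires_malignant="no"),
        MarkerGate("ciliated tumor", ("HYDIN",), requires_malignant="yes"),
        MarkerGate("glioma", ("PTPRZ1", "OLIG2", "AQP4"), requires_malignant="yes"),
    ]
    return MarkerGateConfig(gates=fine)


def marker_annotate(matrix: ExpressionMatrix, malignant: pd.Series,
                    config: MarkerGateConfig | None = None,
                    skip_missing: bool = False) -> pd.DataFrame:
    """Assign per-cell labels by ordered gate evaluation.

    Returns a DataFrame indexed by cell id with columns ``cell_type`` and
    ``proliferating``.  Gates referencing genes absent from the matrix raise a
    configuration error listing them (or are dropped when ``skip_missing``).
    """
    config = config or default_gates()
    lognorm = matrix.require_lognorm()
    malignant = malignant.reindex(matrix.cell_ids, fill_value=False).astype(bool)

    gates = list(config.gates)
    referenced = sorted({g for gate in gates for g in gate.markers_any + gate.forbidden})
    missing = [g for g in referenced if g not in matrix.gene_ids]
    if missing:
        if skip_missing:
            gates = [g for g in gates
                     if all(m in matrix.gene_ids for m in g.markers_any + g.forbidden)]
            log.warning("gates dropped for missing genes: %s", missing)
        else:
            raise ConfigurationError(f"gate genes missing from matrix: {missing}")

    def detected(gene: str) -> np.ndarray:
        row = matrix.gene_ids.get_loc(gene)
        return lognorm[row] > config.detection_threshold

    labels = np.full(matrix.n_cells, UNASSIGNED, dtype=object)
    unset = np.ones(matrix.n_cells, dtype=bool)
    for gate in gates:
        hit = np.zeros(matrix.n_cells, dtype=bool)
        for g in gate.markers_any:
            hit |= detected(g)
        for g in gate.forbidden:
            hit &= ~detected(g)
        if gate.requires_malignant == "yes":
            hit &= malignant.values
        elif gate.requires_malignant == "no":
            hit &= ~malignant.values
        take = hit & unset
        labels[take] = gate.label
        unset &= ~take

    prolif = (detected(config.proliferation_marker)
              if config.proliferation_marker in matrix.gene_ids
              else np.zeros(matrix.n_cells, dtype=bool))
    return pd.DataFrame({"cell_type": labels, "proliferating": prolif},
                        index=matrix.cell_ids)


def majority_vote(labels: pd.Series, clusters: pd.Series) -> pd.Series:
    """Optionally smooth per-cell gate labels to the per-cluster majority."""
    clusters = clusters.reindex(labels.index)
    out = labels.copy()
    for c, block in labels.groupby(clusters):
        out.loc[block.index] = block.mode().iloc[0]
    return out


# ---------------------------------------------------------------------------
# TCGA subtype classification
# ---------------------------------------------------------------------------

SUBTYPES = ("PN", "CL", "MES", "NL")


def load_signatures(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load signature gene sets from a two-column TSV (signature, gene).

    Without a path, the shipped illustrative resource is used; it is a
    synthetic stand-in assembled from widely used subtype markers, not a
    published gene list, and tests never depend on its contents.
    """
    if path is None:
        ref = importlib_resources.files("gliomosaic.resources") / "tcga_signatures.tsv"
        with importlib_resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    sigs = {name: sorted(block["gene"]) for name, block in df.groupby("signature")}
    for name, genes in sigs.items():
        if not genes:
            raise ConfigurationError(f"signature {name} is empty")
    return sigs


def signature_zscores(matrix: ExpressionMatrix,
                      signatures: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-cell signature scores: mean of gene-wise z-scored lognorm."""
    lognorm = matrix.require_lognorm()
    mu = lognorm.mean(axis=1, keepdims=True)
    sd = lognorm.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (lognorm - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    scores = {}
    for name, genes in signatures.items():
        present = [g for g in genes if g in matrix.gene_ids]
        if not present:
            raise ConfigurationError(f"signature {name}: no genes present in matrix")
        rows = matrix.gene_ids.get_indexer(present)
        scores[name] = z[rows].mean(axis=0)
    return pd.DataFrame(scores, index=matrix.cell_ids)


def tcga_classify(matrix: ExpressionMatrix, malignant: pd.Series,
                  signatures: Mapping[str, Sequence[str]] | None = None
                  ) -> pd.DataFrame:
    """Assign each malignant cell to the argmax signature.

    Returns per-cell scores, ``subtype`` (NaN for non-malignant, "ambiguous"
    for exact argmax ties) and ``margin`` (top minus second score).
    """
    if signatures is None:
        signatures = load_signatures()
    malignant = malignant.reindex(matrix.cell_ids, fill_value=False).astype(bool)
    if not malignant.any():
        raise ConfigurationError("no malignant cells to classify")
    scores = signature_zscores(matrix, signatures)
    vals = scores.values
    order = np.argsort(-vals, axis=1)
    top = vals[np.arange(len(vals)), order[:, 0]]
    second = vals[np.arange(len(vals)), order[:, 1]] if vals.shape[1] > 1 else np.full(len(vals), -np.inf)
    names = np.array(scores.columns)
    subtype = names[order[:, 0]].astype(object)
    subtype[np.isclose(top, second)] = AMBIGUOUS
    out = scores.copy()
    out["subtype"] = subtype
    out["margin"] = top - second
    out.loc[~malignant.values, "subtype"] = np.nan
    return out
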