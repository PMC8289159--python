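"""End-to-end orchestration: qc -> normalize -> provisional gate -> CNV ->
subgroups -> malignancy -> mask -> embedding/clusters -> annotation ->
clones -> composition -> cross-talk -> scoring -> survival.

Every stage writes its artifacts once into the output directory; a JSON
manifest records the seed, config hash, input checksums and per-stage output
checksums and shapes (no timestamps, so reruns with the same seed are
byte-comparable).  The expensive stages (CNV inference, embedding) can be
resumed from their serialized outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (default_gates, extended_gates, load_signatures,
                       marker_annotate, tcga_classify)
from .clones import (cluster_subclones, consensus_events, order_clones,
                     sector_composition, clone_differential_expression)
from .cnv import (ArmCNVMatrix, CNVParams, call_malignant, cluster_cnv_subgroups,
                  infer_cnv, resolve_reference_cells, summarize_arms)
from .crosstalk import (ligand_receptor_map, load_lr_pairs, load_m2bneu_genes,
                        signature_score, survival_stratify)
from .embed import (EmbedParams, MaskParams, embed_and_cluster, read_segments,
                    select_hvg, stable_region_mask, write_mask)
from .errors import StageError
from .genome import read_gene_annotation
from .io_qc import QCThresholds, normalize, qc_filter, read_matrix

log = logging.getLogger(__name__)

INPUT_FILES = ("matrix.mtx", "genes.tsv", "barcodes.tsv", "genes_bed.tsv",
               "segments.tsv", "survival.tsv", "cells.tsv")

# per-stage seed offsets so a resumed stage reproduces the original run
STAGE_SEED_OFFSETS = {"embed": 101, "clones": 202}


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    qc: Mapping[str, Any] = field(default_factory=lambda: {
        "min_genes_per_cell": 150, "min_counts_per_cell": 200,
        "max_mito_fraction": 1.0, "min_cells_per_gene": 3})
    normalize_scale: int = 100_000
    cnv: Mapping[str, Any] = field(default_factory=dict)
    mask: Mapping[str, Any] = field(default_factory=dict)
    embed: Mapping[str, Any] = field(default_factory=dict)
    clones_k: int | str = "auto"
    gates: str = "extended"
    signatures_path: str | None = None
    lr_pairs_path: str | None = None
    score_genes_path: str | None = None
    survival_cut: str = "median"
    min_fraction: float = 0.1
    write_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_canonical(self) -> str:
        """Canonical YAML of the analysis parameters (paths excluded, so the
        hash identifies the analysis, not where it ran)."""
        d = {k: (dict(v) if isinstance(v, Mapping) else v)
             for k, v in self.__dict__.items()
             if k not in ("input_dir", "output_dir")}
        return yaml.safe_dump(d, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    in_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    missing = [f for f in INPUT_FILES if not (in_dir / f).exists()]
    if missing:
        raise StageError("validate", "missing-input",
                         f"input files not found: {[str(in_dir / m) for m in missing]}")

    manifest: dict = {
        "tool": "gliomosaic",
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.to_canonical().encode()).hexdigest(),
        "inputs": {f: _sha256(in_dir / f) for f in INPUT_FILES},
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], **shapes):
        manifest["stages"].append({
            "stage": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "shapes": shapes,
        })

    def run_stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise StageError(name, "stage-failure", str(exc)) from exc

    # -- qc + normalize ------------------------------------------------
    def stage_qc():
        matrix = read_matrix(in_dir / "matrix.mtx", in_dir / "genes.tsv",
                             in_dir / "barcodes.tsv")
        matrix, report = qc_filter(matrix, QCThresholds(**dict(config.qc)))
        report.write_tsv(out / "qc_report.tsv")
        normalize(matrix, scale=config.normalize_scale)
        record("qc", [out / "qc_report.tsv"],
               cells=matrix.n_cells, genes=matrix.n_genes)
        return matrix

    matrix = run_stage("qc", stage_qc)
    annotation = read_gene_annotation(in_dir / "genes_bed.tsv")
    cells_meta = pd.read_csv(in_dir / "cells.tsv", sep="\t").set_index("cell_id")
    cells_meta = cells_meta.loc[matrix.cell_ids]

    # -- CNV inference -------------------------------------------------
    cnv_params = CNVParams(**dict(config.cnv))

    def stage_cnv() -> ArmCNVMatrix:
        arm_path = out / "arm_scores.tsv"
        if resume and arm_path.exists():
            df = pd.read_csv(arm_path, sep="\t", index_col=0)
            return ArmCNVMatrix(arm_score=df.loc[matrix.cell_ids])
        cnv = infer_cnv(matrix, annotation, cnv_params)
        arm = summarize_arms(cnv, annotation)
        arm.arm_score.rename_axis("cell_id").to_csv(arm_path, sep="\t")
        return arm

    arm = run_stage("infercnv", stage_cnv)
    record("infercnv", [out / "arm_scores.tsv"], arms=len(arm.arms))

    def stage_subgroups():
        labels = cluster_cnv_subgroups(arm, cnv_params)
        malignant = call_malignant(arm, labels, cnv_params.amp_threshold)
        return labels, malignant

    subgroups, malignant = run_stage("subgroups", stage_subgroups)

    # -- stable-region mask -------------------------------------------
    def stage_mask():
        profiles = read_segments(in_dir / "segments.tsv")
        mask = stable_region_mask(profiles, annotation, MaskParams(**dict(config.mask)))
        write_mask(mask, out / "gene_mask.tsv")
        return mask

    mask = run_stage("mask", stage_mask)
    record("mask", [out / "gene_mask.tsv"], retained=int(mask.sum()))

    # -- embedding -----------------------------------------------------
    embed_params = EmbedParams(**{"seed": config.seed + STAGE_SEED_OFFSETS["embed"],
                                  **dict(config.embed)})

    def stage_embed():
        emb_path, cl_path = out / "embedding.csv", out / "clusters.csv"
        if resume and emb_path.exists() and cl_path.exists():
            coords = pd.read_csv(emb_path, index_col=0)
            labels = pd.read_csv(cl_path, index_col=0)["cluster"]
            return coords, labels
        genes = select_hvg(matrix, mask, embed_params.n_hvg)
        coords, labels = embed_and_cluster(matrix, genes, embed_params)
        coords.rename_axis("cell_id").to_csv(emb_path)
        labels.rename_axis("cell_id").to_frame().to_csv(cl_path)
        return coords, labels

    coords, clusters = run_stage("embed", stage_embed)
    record("embed", [out / "embedding.csv", out / "clusters.csv"],
           clusters=int(pd.Series(clusters).nunique()))

    # -- annotation ----------------------------------------------------
    def stage_annotate():
        gate_cfg = extended_gates() if config.gates == "extended" else default_gates()
        ann = marker_annotate(matrix, malignant, gate_cfg, skip_missing=True)
        sigs = load_signatures(config.signatures_path)
        try:
            tcga = tcga_classify(matrix, malignant, sigs)
            ann["subtype"] = tcga["subtype"]
        except Exception as exc:
            log.warning("TCGA classification skipped: %s", exc)
            ann["subtype"] = np.nan
        return ann

    ann = run_stage("annotate", stage_annotate)

    # -- clones --------------------------------------------------------
    def stage_clones():
        labels = cluster_subclones(arm, malignant, config.clones_k,
                                   cnv_params.amp_threshold, cnv_params.del_threshold)
        events = consensus_events(arm, labels, cnv_params.amp_threshold,
                                  cnv_params.del_threshold)
        tree = order_clones(events)
        tree.to_edge_table().to_csv(out / "clone_tree.tsv", sep="\t", index=False)
        (out / "clone_tree.nwk").write_text(tree.to_newick() + "\n")
        return labels, events, tree

    clone_labels, clone_events, tree = run_stage("clones", stage_clones)
    record("clones", [out / "clone_tree.tsv", out / "clone_tree.nwk"],
           clones=len(tree.nodes))

    # assemble the cell annotation join surface
    table = cells_meta.copy()
    table["cnv_subgroup"] = subgroups
    table["malignant"] = malignant
    table["cell_type"] = ann["cell_type"]
    table["proliferating"] = ann["proliferating"]
    table["subtype"] = ann["subtype"]
    table["clone"] = clone_labels
    table["cluster"] = clusters
    table[["tsne1", "tsne2"]] = coords.iloc[:, :2].values

    def stage_composition():
        comp = sector_composition(table.reset_index(), "sector",
                                  ("cell_type", "clone"))
        comp.to_csv(out / "composition.csv", index=False)
        return comp

    comp = run_stage("composition", stage_composition)
    record("composition", [out / "composition.csv"], sectors=comp["sector"].nunique())

    # -- cross-talk ----------------------------------------------------
    def stage_crosstalk():
        pairs = load_lr_pairs(config.lr_pairs_path)
        edges = ligand_receptor_map(matrix, table, pairs, config.min_fraction)
        edges.to_csv(out / "lr_edges.csv", index=False)
        return edges

    edges = run_stage("crosstalk", stage_crosstalk)
    record("crosstalk", [out / "lr_edges.csv"],
           active_edges=int(edges["active"].sum()) if len(edges) else 0)

    # -- scoring + survival -------------------------------------------
    def stage_score():
        gene_set = load_m2bneu_genes(config.score_genes_path)
        cell_scores = signature_score(matrix, gene_set).scores
        table["m2bneu_score"] = cell_scores
        pseudobulk = pd.DataFrame(
            {pat: matrix.require_lognorm()[:, np.where(table["patient"].values == pat)[0]].mean(axis=1)
             for pat in pd.unique(table["patient"])},
            index=matrix.gene_ids)
        sample_scores = signature_score(pseudobulk, gene_set).scores
        sample_scores.rename_axis("sample").to_frame().to_csv(out / "sample_scores.csv")
        return sample_scores

    sample_scores = run_stage("score", stage_score)
    record("score", [out / "sample_scores.csv"], samples=len(sample_scores))

    def stage_survival():
        survival = pd.read_csv(in_dir / "survival.tsv", sep="\t")
        res = survival_stratify(sample_scores, survival, config.survival_cut)
        stats = pd.DataFrame([{"statistic": res.statistic, "p_value": res.p_value}])
        stats.to_csv(out / "logrank.csv", index=False)
        for name, tbl in res.km_tables.items():
            tbl.to_csv(out / f"km_{name}.csv", index=False)
        return res

    surv_res = run_stage("survival", stage_survival)
    record("survival", [out / "logrank.csv"] +
           [out / f"km_{g}.csv" for g in surv_res.km_tables],
           groups=int(surv_res.groups.nunique()))

    table.rename_axis("cell_id").reset_index().to_csv(out / "cell_annotation.csv",
                                                      index=False)
    record("annotation-table", [out / "cell_annotation.csv"], cells=len(table))

    if config.write_figures:
        from . import figures
        figures.export_all(out, arm, subgroups, coords, clusters, comp, surv_res)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
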