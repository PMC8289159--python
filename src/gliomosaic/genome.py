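"""Gene genomic annotation: coordinates, chromosome-arm assignment, genome order.

A GeneAnnotation is a DataFrame indexed by gene id with columns
``chrom``, ``start``, ``end`` (0-based half-open) and ``arm`` ("p"/"q").
The helper functions here define the single genomic ordering used by the
CNV smoothing and masking stages.  Chromosomes keep their first-appearance
order in the annotation (the simulator and the shipped loaders emit them in
karyotype order already).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

ANNOT_COLUMNS = ["chrom", "start", "end", "arm"]


def arm_key(chrom: str, arm: str) -> str:
    """Canonical arm label, e.g. ('chr7', 'p') -> 'chr7p'."""
    return f"{chrom}{arm}"


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOT_COLUMNS if c not in annotation.columns]
    if missing:
        raise FormatError(f"gene annotation missing columns: {missing}")
    if annotation.index.has_duplicates:
        dup = annotation.index[annotation.index.duplicated()][0]
        raise FormatError(f"duplicate gene id in annotation: {dup!r}")
    if (annotation["end"] <= annotation["start"]).any():
        bad = annotation.index[annotation["end"] <= annotation["start"]][0]
        raise FormatError(f"empty/inverted interval for gene {bad!r}")
    return annotation


def genome_order(annotation: pd.DataFrame) -> pd.Index:
    """Gene ids sorted by (chromosome first-appearance order, start)."""
    chrom_rank = {c: i for i, c in enumerate(pd.unique(annotation["chrom"]))}
    key = annotation.assign(_rank=annotation["chrom"].map(chrom_rank))
    ordered = key.sort_values(["_rank", "start"], kind="stable")
    return ordered.index


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV: chrom, start, end, gene_id, arm (no header)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "arm"])
    df = df.set_index("gene_id")[ANNOT_COLUMNS]
    return validate_annotation(df)


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()
    out = out.rename(columns={out.columns[0]: "gene_id"})
    out[["chrom", "start", "end", "gene_id", "arm"]].to_csv(
        path, sep="\t", header=False, index=False)


def arm_table(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-arm genome-ordered table: chrom, arm, start, end, n_genes."""
    ordered = annotation.loc[genome_order(annotation)]
    keys = [arm_key(c, a) for c, a in zip(ordered["chrom"], ordered["arm"])]
    ordered = ordered.assign(arm_id=keys)
    rows = []
    for aid in pd.unique(ordered["arm_id"]):
        block = ordered[ordered["arm_id"] == aid]
        rows.append({
            "arm_id": aid,
            "chrom": block["chrom"].iloc[0],
            "arm": block["arm"].iloc[0],
            "start": int(block["start"].min()),
            "end": int(block["end"].max()),
            "n_genes": len(block),
        })
    return pd.DataFrame(rows).set_index("arm_id")


def arm_of_genes(annotation: pd.DataFrame) -> pd.Series:
    """Map gene id -> canonical arm label."""
    return pd.Series(
        [arm_key(c, a) for c, a in zip(annotation["chrom"], annotation["arm"])],
        index=annotation.index, name="arm_id")


def true_arm_log2(copies: dict[str, float], arms: list[str]) -> np.ndarray:
    """log2(copy/2) vector over *arms* for a clone's arm->copy map (diploid = 0)."""
    return np.array([np.log2(copies.get(a, 2.0) / 2.0) for a in arms])
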