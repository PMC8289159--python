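"""Parameter-recovery benchmarks: each function generates a synthetic cohort
with known ground truth, runs the corresponding analysis stage, and measures
how well the truth is recovered.  Shared by the test suite and the
acceptance script."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import tcga_classify
from .clones import (cluster_subclones, clone_differential_expression,
                     consensus_events, merge_subgroups_by_events, order_clones)
from .cnv import CNVParams, call_malignant, cluster_cnv_subgroups, infer_cnv, \
    summarize_arms
from .crosstalk import ligand_receptor_map, load_lr_pairs, survival_stratify
from .embed import EmbedParams, MaskParams, mixing_improvement, \
    stable_region_mask
from .genome import true_arm_log2
from .io_qc import normalize
from .synthdata import (CloneSpec, SectorSpec, SimulationConfig,
                        branched_config, crosstalk_config, deconfound_config,
                        default_marker_program, gs1_like_config,
                        hg_like_arm_table, simulate_cohort, simulate_survival,
                        _auto_named_gene_arms, _named_genes_of)

log = logging.getLogger(__name__)


def _arm_scores(cohort, params: CNVParams | None = None):
    normalize(cohort.matrix)
    cnv = infer_cnv(cohort.matrix, cohort.gene_annotation, params or CNVParams())
    return summarize_arms(cnv, cohort.gene_annotation)


# ---------------------------------------------------------------------------
# CNV dose recovery (correlation, subgrouping, malignancy)
# ---------------------------------------------------------------------------

@dataclass
class DoseRecovery:
    median_pearson_r: float
    subgroup_ari: float
    malignant_accuracy: float
    n_cells: int


def dose_recovery(seed: int, n_cells: int = 2000, n_genes: int = 5000
                  ) -> DoseRecovery:
    """GS1-like linear-chain cohort: per-cell correlation of arm scores with
    true log2(copy/2), CNV-subtype ARI (clusters merged by consensus events),
    and malignant-call accuracy."""
    from sklearn.metrics import adjusted_rand_score

    cohort = simulate_cohort(gs1_like_config(seed=seed, n_cells=n_cells,
                                             n_genes=n_genes))
    arm = _arm_scores(cohort)
    truth = cohort.truth.cells
    arms = list(arm.arms)

    mal_mask = (truth["true_clone"] != "CN-0").values
    rs = []
    for cid in truth.index[mal_mask]:
        clone = truth.loc[cid, "true_clone"]
        tv = true_arm_log2(cohort.truth.clone_copies[clone], arms)
        rs.append(np.corrcoef(tv, arm.arm_score.loc[cid].values)[0, 1])

    labels = cluster_cnv_subgroups(arm, CNVParams(n_subgroups=5))
    merged = merge_subgroups_by_events(arm, labels)
    ari = adjusted_rand_score(truth["true_clone"].values, merged.values)

    calls = call_malignant(arm, labels)
    acc = float((calls.values == mal_mask).mean())
    return DoseRecovery(float(np.median(rs)), float(ari), acc, n_cells)


# ---------------------------------------------------------------------------
# Clone tree recovery
# ---------------------------------------------------------------------------

def _seeded_event_sets(cohort) -> list[tuple]:
    cfg = cohort.config
    sets = []
    for cid, copies in cohort.truth.clone_copies.items():
        events = tuple(sorted(
            (a, "amp" if c > 2 else "del")
            for a, c in copies.items() if c != 2.0))
        sets.append(events)
    return sorted(sets, key=lambda s: (len(s), s))


def _tree_is_chain(tree) -> bool:
    node = tree.root
    seen = 1
    while tree.children(node):
        kids = tree.children(node)
        if len(kids) != 1:
            return False
        node = kids[0]
        seen += 1
    return seen == len(tree.nodes)


def linear_tree_recovered(seed: int, n_cells: int = 2000,
                          n_genes: int = 5000) -> bool:
    """Full-stack recovery of the seeded 3-clone linear chain."""
    cohort = simulate_cohort(gs1_like_config(seed=seed, n_cells=n_cells,
                                             n_genes=n_genes))
    arm = _arm_scores(cohort)
    truth = cohort.truth.cells
    malignant = truth["true_clone"] != "CN-0"
    labels = cluster_subclones(arm, malignant, k=3)
    tree = order_clones(consensus_events(arm, labels))
    if len(tree.nodes) != 3 or not _tree_is_chain(tree):
        return False
    inferred = sorted((tuple(sorted(ev)) for ev in tree.nodes.values()),
                      key=lambda s: (len(s), s))
    return inferred == _seeded_event_sets(cohort)


def branched_tree_recovered(seed: int, n_cells: int = 2000,
                            n_genes: int = 5000) -> bool:
    """Full-stack recovery of the seeded 2-branch tree ({X},{X,Y},{X,Z}),
    cross-checked against a brute-force containment oracle."""
    cohort = simulate_cohort(branched_config(seed=seed, n_cells=n_cells,
                                             n_genes=n_genes))
    arm = _arm_scores(cohort)
    truth = cohort.truth.cells
    malignant = truth["true_clone"] != "CN-0"
    labels = cluster_subclones(arm, malignant, k=3)
    events = consensus_events(arm, labels)
    tree = order_clones(events)
    if len(tree.nodes) != 3:
        return False
    inferred = sorted((tuple(sorted(ev)) for ev in tree.nodes.values()),
                      key=lambda s: (len(s), s))
    if inferred != _seeded_event_sets(cohort):
        return False
    # brute-force containment oracle over the inferred sets
    sets = {c: frozenset(ev) for c, ev in tree.nodes.items()}
    root = min(sets, key=lambda c: len(sets[c]))
    expected_children = {c for c in sets
                         if c != root and sets[root] < sets[c]
                         and not any(sets[root] < sets[m] < sets[c]
                                     for m in sets if m not in (root, c))}
    return tree.root == root and set(tree.children(root)) == expected_children \
        and all(not tree.children(c) for c in expected_children)


# ---------------------------------------------------------------------------
# Embedding de-confounding
# ---------------------------------------------------------------------------

def mixing_gain(seed: int) -> tuple[float, float]:
    """(masked, unmasked) patient-mixing entropy on the de-confounding cohort."""
    cohort = simulate_cohort(deconfound_config(seed=seed))
    normalize(cohort.matrix)
    mask = stable_region_mask(cohort.bulk_profiles, cohort.gene_annotation,
                              MaskParams())
    ann = cohort.annotation.rename(columns={"true_type": "cell_type"})
    return mixing_improvement(cohort.matrix, ann, mask,
                              EmbedParams(n_hvg=800, n_pcs=20, seed=seed))


# ---------------------------------------------------------------------------
# Subtype classifier recovery
# ---------------------------------------------------------------------------

SUBTYPE_SIGNATURES = {
    name: tuple(f"SIG{name}{i}" for i in range(8))
    for name in ("PN", "CL", "MES", "NL")
}


def subtype_recovery_config(seed: int, cells_per_subtype: int = 500,
                            n_genes: int = 1200) -> SimulationConfig:
    """Four clones, each spiked with one subtype signature program."""
    arm_table = hg_like_arm_table(n_genes)
    clones = [
        CloneSpec("T-PN", None, frozenset({("chr7", "amp")})),
        CloneSpec("T-CL", "T-PN", frozenset({("chr2", "amp")})),
        CloneSpec("T-MES", "T-PN", frozenset({("chr5", "del")})),
        CloneSpec("T-NL", "T-PN", frozenset({("chr10", "del")})),
    ]
    marker = default_marker_program()
    for name, genes in SUBTYPE_SIGNATURES.items():
        marker[f"T-{name}"] = [(genes, 4.0)]
    names = _named_genes_of(marker, {})
    n_tumor = 4 * cells_per_subtype
    total = int(n_tumor / 0.9)
    mix = {f"T-{n}": cells_per_subtype / total for n in SUBTYPE_SIGNATURES}
    mix["normal-glia"] = 1.0 - sum(mix.values())
    sig_genes = [g for genes in SUBTYPE_SIGNATURES.values() for g in genes]
    return SimulationConfig(
        arm_table=arm_table, clone_tree_spec=clones,
        sectors=[SectorSpec("s1", "tumoral", mix)],
        n_patients=1, cells_per_sector=total,
        marker_program=marker,
        gene_baseline={g: 2.0 for g in sig_genes},
        named_gene_arms=_auto_named_gene_arms(
            arm_table, names, ("chr2", "chr5", "chr7", "chr10")),
        seed=seed,
    )


def subtype_recovery(seed: int, cells_per_subtype: int = 500) -> float:
    """Accuracy of the signature classifier on four spiked programs, using
    the seeded malignancy truth."""
    cohort = simulate_cohort(subtype_recovery_config(seed, cells_per_subtype))
    normalize(cohort.matrix)
    truth = cohort.truth.cells
    malignant = pd.Series((truth["true_clone"] != "CN-0").values,
                          index=truth.index)
    sigs = {k: list(v) for k, v in SUBTYPE_SIGNATURES.items()}
    out = tcga_classify(cohort.matrix, malignant, sigs)
    mal = malignant.values
    expected = truth.loc[mal, "true_clone"].str.replace("T-", "", regex=False)
    return float((out.loc[mal, "subtype"] == expected).mean())


# ---------------------------------------------------------------------------
# Differential expression calibration
# ---------------------------------------------------------------------------

def de_cohort(seed: int, n_cells_per_group: int, seeded_genes: int = 30,
              fold: float = 4.0, with_program: bool = True):
    """Two clones with identical copy states; clone B optionally carries a
    fold-change program on dedicated genes."""
    n_genes = 1200
    arm_table = hg_like_arm_table(n_genes)
    program_genes = tuple(f"DEG{i}" for i in range(seeded_genes))
    marker = {}
    if with_program:
        marker["T-B"] = [(program_genes, fold)]
    names = _named_genes_of(marker, {}) if marker else []
    clones = [CloneSpec("T-A", None, frozenset({("chr7", "amp")})),
              CloneSpec("T-B", "T-A", frozenset())]
    total = 2 * n_cells_per_group
    cfg = SimulationConfig(
        arm_table=arm_table, clone_tree_spec=clones,
        sectors=[SectorSpec("s1", "tumoral", {"T-A": 0.5, "T-B": 0.5})],
        n_patients=1, cells_per_sector=total,
        marker_program=marker,
        gene_baseline={g: 2.0 for g in program_genes} if with_program else None,
        named_gene_arms=_auto_named_gene_arms(arm_table, names, ("chr7",))
        if names else None,
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    normalize(cohort.matrix)
    return cohort, program_genes


def de_null_has_no_hits(seed: int, n_per_group: int = 50) -> bool:
    """Split one clone at random; True when no gene is BH-significant."""
    cohort, _ = de_cohort(seed, n_per_group, with_program=False)
    truth = cohort.truth.cells
    cells_a = truth.index[truth["true_clone"] == "T-A"]
    rng = np.random.default_rng(seed + 77_000)
    half = rng.permutation(len(cells_a))[: len(cells_a) // 2]
    labels = pd.Series("H2", index=cohort.matrix.cell_ids)
    labels.loc[cells_a[half]] = "H1"
    labels.loc[truth.index[truth["true_clone"] != "T-A"]] = "other"
    table = clone_differential_expression(cohort.matrix, labels, ["H1"], ["H2"])
    return int(table["significant"].sum()) == 0


def de_recall(seed: int, n_per_group: int = 100) -> float:
    """Recall of seeded 4-fold genes between two otherwise identical clones."""
    cohort, program_genes = de_cohort(seed, n_per_group)
    truth = cohort.truth.cells
    labels = pd.Series(truth["true_clone"].values, index=cohort.matrix.cell_ids)
    table = clone_differential_expression(cohort.matrix, labels, ["T-B"], ["T-A"])
    hits = table[table["significant"] & (table["lfc"] > 0)]["gene"]
    return float(len(set(hits) & set(program_genes)) / len(program_genes))


# ---------------------------------------------------------------------------
# Cross-talk fixture
# ---------------------------------------------------------------------------

def expected_active_edges(cfg: SimulationConfig, pairs: pd.DataFrame
                          ) -> set[tuple[str, str, str, str]]:
    """Brute-force expectation from the seeded programs: an edge is expected
    active iff some program gives the ligand to the sender type and the
    receptor to the receiver type."""
    sources: dict[str, set[str]] = {}

    def add(gene: str, key: str) -> None:
        label = "malignant" if key.startswith("CN-") or key.startswith("T-") \
            or key == "malignant" else key
        sources.setdefault(gene, set()).add(label)

    for key, programs in cfg.marker_program.items():
        for genes, _ in programs:
            for g in genes:
                add(g, key)
    for (lig, rec), (sender, receiver, _) in cfg.lr_program.items():
        add(lig, sender)
        add(rec, receiver)

    expected = set()
    for _, row in pairs.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        for s in sources.get(lig, ()):  # noqa: B905
            for r in sources.get(rec, ()):
                expected.add((lig, rec, s, r))
    return expected


def crosstalk_fixture(seed: int) -> tuple[set, set, pd.DataFrame]:
    """(observed active edges, expected active edges, full edge table)."""
    cfg = crosstalk_config(seed=seed)
    cohort = simulate_cohort(cfg)
    normalize(cohort.matrix)
    ann = cohort.annotation.rename(columns={"true_type": "cell_type"})
    pairs = load_lr_pairs()
    edges = ligand_receptor_map(cohort.matrix, ann, pairs, min_fraction=0.1)
    observed = {tuple(r) for r in
                edges.loc[edges["active"],
                          ["ligand", "receptor", "sender", "receiver"]].values}
    expected = expected_active_edges(cfg, pairs)
    present = set(cohort.matrix.gene_ids)
    expected = {e for e in expected if e[0] in present and e[1] in present}
    return observed, expected, edges


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def logrank_power(seed: int, n_samples: int = 200, hazard_ratio: float = 2.0,
                  n_replicates: int = 100) -> float:
    """Fraction of replicate cohorts with log-rank p < 0.05 between seeded
    high/low score groups."""
    rng = np.random.default_rng(seed)
    hits = 0
    scores = pd.Series(np.r_[np.ones(n_samples // 2), np.zeros(n_samples // 2)],
                       index=[f"s{i}" for i in range(n_samples)])
    for _ in range(n_replicates):
        surv = simulate_survival(scores, hazard_ratio, 1.0 / 24.0, 60.0, rng)
        res = survival_stratify(scores, surv, "median")
        hits += res.p_value < 0.05
    return hits / n_replicates
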