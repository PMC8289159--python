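"""Subclone calling, event discretization, clonal-order reconstruction,
per-sector composition and inter-clone differential expression.

A clone is a group of malignant cells sharing a consensus set of arm-level
events (amplification/deletion per chromosome arm).  Clones are ordered by
event accumulation: clone A is ancestral to clone B when A's event set is a
strict subset of B's, under the assumption that arm-level events are not lost
once acquired.  The resulting parent-child graph is the transitive reduction
of the containment order; incomparable clones hang as siblings under the
clone carrying the intersection of their events (a synthetic unobserved
ancestor is introduced if no observed clone does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import chi2_contingency, mannwhitneyu
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InvariantError
from .genome import arm_of_genes
from .cnv import ArmCNVMatrix
from .io_qc import ExpressionMatrix

log = logging.getLogger(__name__)

Event = tuple[str, str]  # (arm id, "amp"|"del")

NON_MALIGNANT_LABEL = "CN-0"


@dataclass(frozen=True)
class CloneEventSet:
    clone_id: str
    events: frozenset[Event]

    def __post_init__(self) -> None:
        arms = [a for a, _ in self.events]
        if len(arms) != len(set(arms)):
            raise ConfigurationError(
                f"clone {self.clone_id}: more than one state for an arm")


@dataclass
class CloneTree:
    """Rooted clone graph; edge annotations are the events gained on the edge."""

    nodes: dict[str, frozenset[Event]]
    edges: list[tuple[str, str, frozenset[Event]]]
    root: str
    merged: dict[str, list[str]] = field(default_factory=dict)

    def children(self, clone: str) -> list[str]:
        return [c for p, c, _ in self.edges if p == clone]

    def parent(self, clone: str) -> str | None:
        for p, c, _ in self.edges:
            if c == clone:
                return p
        return None

    def validate(self) -> None:
        """Assert tree-ness: unique parents, acyclic, all reachable from root."""
        seen_children = [c for _, c, _ in self.edges]
        if len(seen_children) != len(set(seen_children)):
            raise InvariantError("a clone has two parents")
        reached = {self.root}
        frontier = [self.root]
        while frontier:
            nxt = []
            for p in frontier:
                for c in self.children(p):
                    if c in reached:
                        raise InvariantError("cycle in clone tree")
                    reached.add(c)
                    nxt.append(c)
            frontier = nxt
        if reached != set(self.nodes):
            raise InvariantError("clone tree has unreachable nodes")

    def to_edge_table(self) -> pd.DataFrame:
        rows = [{"parent": p, "child": c,
                 "gained_events": ";".join(sorted(f"{a}:{s}" for a, s in ev))}
                for p, c, ev in self.edges]
        return pd.DataFrame(rows, columns=["parent", "child", "gained_events"])

    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            kids = self.children(node)
            label = node
            gained = next((ev for p, c, ev in self.edges if c == node), None)
            comment = ""
            if gained:
                comment = "[&&events=" + "|".join(
                    sorted(f"{a}:{s}" for a, s in gained)) + "]"
            if not kids:
                return f"{label}{comment}"
            return "(" + ",".join(fmt(k) for k in kids) + f"){label}{comment}"
        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Clone calling
# ---------------------------------------------------------------------------

def cluster_subclones(arm: ArmCNVMatrix, malignant: pd.Series,
                      k: int | str = "auto",
                      amp_threshold: float = 0.1,
                      del_threshold: float = -0.1) -> pd.Series:
    """Ward/Euclidean clustering of malignant cells' arm scores into clones.

    Labels are CN-1..CN-k ordered by increasing consensus event count
    (ties broken by raw cluster id); non-malignant cells get CN-0.
    """
    malignant = malignant.reindex(arm.arm_score.index, fill_value=False)
    mal_ids = arm.arm_score.index[malignant.values.astype(bool)]
    if len(mal_ids) < 2:
        raise ConfigurationError("need >= 2 malignant cells to call subclones")
    X = arm.arm_score.loc[mal_ids].values
    if k == 1:
        raw = np.ones(len(mal_ids), dtype=int)
    else:
        link = sch.linkage(X, method="ward", metric="euclidean")
        if isinstance(k, str) and k == "auto":
            best_k, best_s = 2, -np.inf
            for kk in range(2, min(8, len(mal_ids) - 1) + 1):
                lab = sch.fcluster(link, kk, criterion="maxclust")
                if len(np.unique(lab)) < 2:
                    continue
                s = silhouette_score(X, lab)
                if s > best_s:
                    best_k, best_s = kk, s
            k = best_k
        if k > len(mal_ids):
            raise ConfigurationError(f"k={k} exceeds malignant cell count {len(mal_ids)}")
        raw = sch.fcluster(link, k, criterion="maxclust")

    # order raw clusters by consensus event count
    counts = {}
    for lab in np.unique(raw):
        member_mean = arm.arm_score.loc[mal_ids[raw == lab]].mean(axis=0)
        n_ev = int(((member_mean >= amp_threshold) | (member_mean <= del_threshold)).sum())
        counts[lab] = n_ev
    order = sorted(np.unique(raw), key=lambda lab: (counts[lab], lab))
    rename = {lab: f"CN-{i + 1}" for i, lab in enumerate(order)}

    out = pd.Series(NON_MALIGNANT_LABEL, index=arm.arm_score.index, name="clone")
    out.loc[mal_ids] = [rename[lab] for lab in raw]
    return out


def consensus_events(arm: ArmCNVMatrix, labels: pd.Series,
                     amp_threshold: float = 0.1,
                     del_threshold: float = -0.1) -> dict[str, CloneEventSet]:
    """Per-clone consensus arm events from mean arm scores.

    amp when mean >= amp_threshold (inclusive), del when mean <= del_threshold.
    The non-malignant pool CN-0 is excluded.
    """
    labels = labels.reindex(arm.arm_score.index)
    out: dict[str, CloneEventSet] = {}
    for lab in pd.unique(labels):
        if lab == NON_MALIGNANT_LABEL:
            continue
        mean = arm.arm_score.loc[labels.index[labels == lab]].mean(axis=0)
        events = frozenset(
            [(a, "amp") for a in mean.index[mean >= amp_threshold]] +
            [(a, "del") for a in mean.index[mean <= del_threshold]])
        out[str(lab)] = CloneEventSet(str(lab), events)
    return out


def merge_subgroups_by_events(arm: ArmCNVMatrix, labels: pd.Series,
                              amp_threshold: float = 0.1,
                              del_threshold: float = -0.1) -> pd.Series:
    """Relabel clusters that share an identical consensus event set.

    Hierarchical clustering routinely splits CNV-equivalent cells by
    expression program (e.g. diploid immune vs diploid glia); for CNV
    subtyping those clusters are the same group.  Labels become G1..Gk in
    order of increasing event count.
    """
    ev = consensus_events(arm, labels, amp_threshold, del_threshold)
    sig = {lab: tuple(sorted(es.events)) for lab, es in ev.items()}
    uniq = sorted(set(sig.values()), key=lambda s: (len(s), s))
    names = {s: f"G{i + 1}" for i, s in enumerate(uniq)}
    return labels.map(lambda l: names[sig[str(l)]]).rename("cnv_subtype")


# ---------------------------------------------------------------------------
# Clonal ordering
# ---------------------------------------------------------------------------

SYNTHETIC_ANCESTOR = "CN-anc"


def _transitive_reduction(nodes: Sequence[str],
                          contains: Mapping[tuple[str, str], bool]
                          ) -> list[tuple[str, str]]:
    """Edges a->b where a strictly contained in b with no intermediate."""
    edges = []
    for a in nodes:
        for b in nodes:
            if a == b or not contains[(a, b)]:
                continue
            if any(contains[(a, m)] and contains[(m, b)]
                   for m in nodes if m not in (a, b)):
                continue
            edges.append((a, b))
    return edges


def order_clones(event_sets: Mapping[str, CloneEventSet] | Sequence[CloneEventSet]
                 ) -> CloneTree:
    """Order clones by event accumulation into a rooted tree.

    Edges follow strict-subset containment after transitive reduction; the
    root is the minimal event set (ties by lexicographic clone id); clones
    with identical event sets are merged with a warning; parentless clones
    attach under a synthetic ancestor holding the intersection of their
    events when no observed clone equals it.
    """
    if not isinstance(event_sets, Mapping):
        event_sets = {e.clone_id: e for e in event_sets}
    if not event_sets:
        raise ConfigurationError("need >= 1 clone")

    # merge identical event sets
    nodes: dict[str, frozenset[Event]] = {}
    merged: dict[str, list[str]] = {}
    by_events: dict[frozenset[Event], str] = {}
    for cid in sorted(event_sets):
        ev = frozenset(event_sets[cid].events)
        if ev in by_events:
            keeper = by_events[ev]
            merged.setdefault(keeper, []).append(cid)
            log.warning("clones %s and %s have identical event sets; merged", keeper, cid)
        else:
            by_events[ev] = cid
            nodes[cid] = ev

    ids = sorted(nodes, key=lambda c: (len(nodes[c]), c))
    contains = {(a, b): nodes[a] < nodes[b] for a in ids for b in ids}
    edges = _transitive_reduction(ids, contains)

    # a clone may contain two incomparable smaller clones (a "diamond"); the
    # accumulation model admits one parent, so keep the maximal one (most
    # shared events; ties by clone id)
    by_child: dict[str, list[str]] = {}
    for p, c in edges:
        by_child.setdefault(c, []).append(p)
    edges = [(max(ps, key=lambda p: (len(nodes[p]), p)), c)
             for c, ps in by_child.items()]

    children = {c for _, c in edges}
    parentless = [c for c in ids if c not in children]
    if len(parentless) == 1:
        root = parentless[0]
    else:
        inter = frozenset.intersection(*(nodes[c] for c in parentless))
        owner = next((c for c in ids if nodes[c] == inter), None)
        if owner is not None and owner in parentless:
            root = owner
            edges += [(root, c) for c in parentless if c != root]
        else:
            root = SYNTHETIC_ANCESTOR
            nodes[root] = inter
            edges += [(root, c) for c in parentless]

    tree = CloneTree(
        nodes=nodes,
        edges=[(p, c, frozenset(nodes[c] - nodes[p])) for p, c in edges],
        root=root,
        merged=merged,
    )
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Composition and differential expression
# ---------------------------------------------------------------------------

def sector_composition(annotation_table: pd.DataFrame,
                       sector_col: str = "sector",
                       columns: Sequence[str] = ("cell_type", "clone")
                       ) -> pd.DataFrame:
    """Long-format counts and simplex fractions per sector for each column.

    Output columns: sector, variable, value, count, fraction; fractions sum
    to 1 per (sector, variable).
    """
    cols = [c for c in columns if c in annotation_table.columns]
    if not cols:
        raise ConfigurationError(f"no composition columns found among {columns}")
    rows = []
    for sector, block in annotation_table.groupby(sector_col, sort=False):
        if len(block) == 0:  # pragma: no cover
            log.warning("sector %s has zero cells; omitted", sector)
            continue
        for col in cols:
            counts = block[col].value_counts()
            total = counts.sum()
            for value, n in counts.items():
                rows.append({"sector": sector, "variable": col, "value": value,
                             "count": int(n), "fraction": n / total})
    return pd.DataFrame(rows)


def clone_differential_expression(matrix: ExpressionMatrix, labels: pd.Series,
                                  group_a: Sequence[str], group_b: Sequence[str],
                                  alpha: float = 0.05,
                                  annotation: pd.DataFrame | None = None,
                                  clone_events: Mapping[str, CloneEventSet] | None = None
                                  ) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two clone groups.

    Returns a gene table ranked by adjusted p with columns: gene, lfc
    (mean lognorm difference A - B, natural log scale), p, p_adj,
    significant (p_adj < alpha) and cnv_dose (True when the gene lies on an
    arm whose consensus copy state differs between the groups — expression
    changes there may be pure dosage).
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ConfigurationError(f"groups overlap: {sorted(group_a & group_b)}")
    labels = labels.reindex(matrix.cell_ids)
    idx_a = np.where(labels.isin(group_a).values)[0]
    idx_b = np.where(labels.isin(group_b).values)[0]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ConfigurationError("each group needs >= 3 cells")
    lognorm = matrix.require_lognorm()
    a = lognorm[:, idx_a]
    b = lognorm[:, idx_b]
    stat, p = mannwhitneyu(a, b, axis=1, alternative="two-sided")
    p = np.asarray(p, dtype=float)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    lfc = a.mean(axis=1) - b.mean(axis=1)

    dose = np.zeros(matrix.n_genes, dtype=bool)
    if annotation is not None and clone_events is not None:
        def states(group: set[str]) -> dict[str, frozenset[Event]]:
            evs = [clone_events[g].events for g in group if g in clone_events]
            union = frozenset().union(*evs) if evs else frozenset()
            return union
        ev_a, ev_b = states(group_a), states(group_b)
        diff_arms = {a_ for a_, _ in ev_a ^ ev_b}
        arm_map = arm_of_genes(annotation).reindex(matrix.gene_ids)
        dose = arm_map.isin(diff_arms).values

    out = pd.DataFrame({
        "gene": matrix.gene_ids,
        "lfc": lfc,
        "p": p,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
        "cnv_dose": dose,
    }).sort_values(["p_adj", "p"], kind="stable").reset_index(drop=True)
    return out


def composition_gof(observed: pd.DataFrame, expected: Mapping[str, Mapping[str, float]],
                    variable: str = "cell_type") -> float:
    """Aggregate chi-square goodness-of-fit p of observed sector compositions
    against expected mixtures (testing the generator contract)."""
    from scipy.stats import chisquare
    stats, dofs = 0.0, 0
    obs = observed[observed["variable"] == variable]
    for sector, mix in expected.items():
        block = obs[obs["sector"] == sector]
        total = block["count"].sum()
        cats = [k for k, f in mix.items() if f > 0]
        o = np.array([block.loc[block["value"] == c, "count"].sum() for c in cats],
                     dtype=float)
        e = np.array([mix[c] * total for c in cats])
        keep = e > 0
        s, _ = chisquare(o[keep], e[keep] * o[keep].sum() / e[keep].sum())
        stats += s
        dofs += keep.sum() - 1
    from scipy.stats import chi2
    return float(chi2.sf(stats, dofs))
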