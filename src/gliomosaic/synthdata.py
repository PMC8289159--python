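"""Synthetic multi-sector glioma cohorts with known ground truth.

The generator emulates the structure of a multi-sector biopsy study so that
every downstream stage is testable by parameter recovery: negative-binomial
(gamma-Poisson) counts with lognormal library sizes; cell-type marker
programs (fold changes on named marker genes); a rooted subclone tree whose
arm-level copy states multiply expected expression as (copy/2)**alpha (the
dosage effect); sector-specific cell-type mixtures (macrophage-rich core,
microglia-rich periphery); co-expressed ligand/receptor programs; bulk
copy-number segments derived from the simulated cell mixtures; and
exponential survival times whose hazard scales with the seeded
M2b-macrophage/neutrophil burden.

No distributional choice here is taken from a real cohort — the generator is
a fully specified stand-in with closed-form moments, which is exactly what
makes oracle tests possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .embed import BulkCopyNumberProfile, write_segments
from .errors import ConfigurationError
from .genome import arm_key, write_gene_annotation
from .io_qc import ExpressionMatrix, write_matrix

log = logging.getLogger(__name__)

MALIGNANT_TYPE = "malignant"
TME_TYPES = ("normal-glia", "microglia", "macrophage", "M2b", "lymphocyte",
             "neutrophil")
SCORE_TYPES = ("M2b", "neutrophil")

GENE_LENGTH = 1_000
GENE_STRIDE = 2_000
CENTROMERE_GAP = 10_000


@dataclass(frozen=True)
class CloneSpec:
    """One node of the seeded subclone tree; added_events are (arm-or-chrom,
    'amp'|'del') newly acquired relative to the parent."""

    clone_id: str
    parent_id: str | None
    added_events: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class SectorSpec:
    """One biopsy sector replicated in every patient (unless per-patient
    sectors are given): name, class label, and a cell-type/clone simplex."""

    name: str
    sector_class: str  # tumoral | peritumoral | adjacent
    mixture: Mapping[str, float]


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort; see module docstring."""

    arm_table: list[tuple[str, str, int]]
    clone_tree_spec: list[CloneSpec] | dict[str, list[CloneSpec]]
    sectors: list[SectorSpec] | dict[str, list[SectorSpec]]
    n_patients: int = 4
    cells_per_sector: int = 55
    dose_exponent: float = 1.0
    amp_copy: float = 3.0
    del_copy: float = 1.0
    marker_program: Mapping[str, Sequence[tuple[tuple[str, ...], float]]] = field(
        default_factory=dict)
    lr_program: Mapping[tuple[str, str], tuple[str, str, float]] = field(
        default_factory=dict)
    nb_dispersion: float = 0.3
    libsize_meanlog: float = 0.0
    libsize_sdlog: float = 0.25
    baseline_meanlog: float = 0.5
    baseline_sdlog: float = 1.0
    marker_off_mean: float = 0.02
    gene_baseline: Mapping[str, float] | None = None  # per-gene overrides
    named_gene_arms: Mapping[str, str] | None = None
    hazard_ratio_per_score_unit: float = 2.0
    baseline_hazard: float = 1.0 / 24.0
    censor_horizon: float = 60.0
    seed: int = 0

    # ------------------------------------------------------------------
    def patient_ids(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    def sectors_for(self, patient: str) -> list[SectorSpec]:
        if isinstance(self.sectors, dict):
            return self.sectors[patient]
        return list(self.sectors)

    def clone_specs_for(self, patient: str) -> list[CloneSpec]:
        if isinstance(self.clone_tree_spec, dict):
            return self.clone_tree_spec[patient]
        return list(self.clone_tree_spec)

    def arm_ids(self) -> list[str]:
        return [arm_key(c, a) for c, a, _ in self.arm_table]

    def expand_event_arm(self, token: str) -> list[str]:
        """'chr7' -> all arms of chr7; 'chr7p' -> ['chr7p']."""
        ids = self.arm_ids()
        if token in ids:
            return [token]
        arms = [a for a in ids if a.startswith(token) and a[len(token):] in ("p", "q")]
        if not arms:
            raise ConfigurationError(f"event arm {token!r} not in arm table")
        return arms

    def named_genes(self) -> list[str]:
        names: list[str] = []
        for programs in self.marker_program.values():
            for genes, _ in programs:
                names.extend(genes)
        for (lig, rec) in self.lr_program:
            names.extend([lig, rec])
        seen = set()
        out = []
        for n in names:
            if n not in seen:
                seen.add(n)
                out.append(n)
        return out

    def validate(self) -> None:
        seen_arms = set()
        for chrom, arm, n in self.arm_table:
            if (chrom, arm) in seen_arms:
                raise ConfigurationError(f"duplicate arm table entry ({chrom}, {arm})")
            seen_arms.add((chrom, arm))
            if n < 1:
                raise ConfigurationError(f"arm ({chrom}, {arm}) needs >= 1 gene")
        if not self.arm_table:
            raise ConfigurationError("arm_table is empty")
        all_clone_ids: list[str] = []
        for patient in self.patient_ids():
            specs = self.clone_specs_for(patient)
            self._validate_tree(specs)
            all_clone_ids.extend(s.clone_id for s in specs)
            clone_ids = {s.clone_id for s in specs}
            for sector in self.sectors_for(patient):
                mix = dict(sector.mixture)
                if not mix:
                    raise ConfigurationError(f"sector {sector.name}: empty mixture")
                if abs(sum(mix.values()) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"sector {sector.name}: mixture sums to {sum(mix.values())}")
                if any(f < 0 for f in mix.values()):
                    raise ConfigurationError(f"sector {sector.name}: negative fraction")
                for key in mix:
                    if key not in TME_TYPES and key not in clone_ids:
                        raise ConfigurationError(
                            f"sector {sector.name}: unknown mixture key {key!r}")
        if isinstance(self.clone_tree_spec, dict):
            if len(all_clone_ids) != len(set(all_clone_ids)):
                raise ConfigurationError("clone ids must be globally unique")
        for p in (self.dose_exponent, self.nb_dispersion,
                  self.hazard_ratio_per_score_unit):
            if p <= 0:
                raise ConfigurationError("dose/dispersion/hazard-ratio must be positive")

    def _validate_tree(self, specs: list[CloneSpec]) -> None:
        roots = [s for s in specs if s.parent_id is None]
        if len(roots) != 1:
            raise ConfigurationError(
                f"clone tree must have exactly one root, got {len(roots)}")
        by_id = {s.clone_id: s for s in specs}
        if len(by_id) != len(specs):
            raise ConfigurationError("duplicate clone ids in tree spec")
        for s in specs:
            if s.parent_id is not None and s.parent_id not in by_id:
                raise ConfigurationError(f"clone {s.clone_id}: unknown parent {s.parent_id}")
            # walk to root, collecting ancestor arms; also detects cycles
            ancestor_arms: set[str] = set()
            cur, hops = s, 0
            while cur.parent_id is not None:
                cur = by_id[cur.parent_id]
                for token, _ in cur.added_events:
                    ancestor_arms.update(self.expand_event_arm(token))
                hops += 1
                if hops > len(specs):
                    raise ConfigurationError("cycle in clone tree spec")
            own = set()
            for token, _ in s.added_events:
                own.update(self.expand_event_arm(token))
            if own & ancestor_arms:
                raise ConfigurationError(
                    f"clone {s.clone_id} re-states arms already evented by an "
                    f"ancestor: {sorted(own & ancestor_arms)}")

    def clone_copies(self, patient: str) -> dict[str, dict[str, float]]:
        """arm -> copy per clone: union of events along the root path applied
        to baseline 2 (amp -> amp_copy, del -> del_copy)."""
        specs = {s.clone_id: s for s in self.clone_specs_for(patient)}
        out: dict[str, dict[str, float]] = {}
        for cid, spec in specs.items():
            copies = {a: 2.0 for a in self.arm_ids()}
            cur: CloneSpec | None = spec
            while cur is not None:
                for token, state in cur.added_events:
                    for a in self.expand_event_arm(token):
                        copies[a] = self.amp_copy if state == "amp" else self.del_copy
                cur = specs.get(cur.parent_id) if cur.parent_id else None
            out[cid] = copies
        return out


@dataclass
class GroundTruth:
    cells: pd.DataFrame                 # index cell_id: patient, sector, sector_class, true_type, true_clone
    clone_copies: dict[str, dict[str, float]]   # clone -> arm -> copy (global ids)
    sector_mixtures: dict[tuple[str, str], dict[str, float]]
    baseline_means: pd.Series
    sample_scores: pd.Series            # per patient standardized M2bNeu burden
    sample_hazards: pd.Series


@dataclass
class SimulatedCohort:
    matrix: ExpressionMatrix
    annotation: pd.DataFrame            # truth-backed CellAnnotationTable
    bulk_profiles: list[BulkCopyNumberProfile]
    survival: pd.DataFrame              # sample, time, event
    truth: GroundTruth
    gene_annotation: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.matrix, out)
        write_gene_annotation(self.gene_annotation, out / "genes_bed.tsv")
        write_segments(self.bulk_profiles, out / "segments.tsv")
        self.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
        self.annotation.rename_axis("cell_id").reset_index().to_csv(
            out / "cells.tsv", sep="\t", index=False)
        rows = [{"clone": c, "arm": a, "copy": v}
                for c, arms in self.truth.clone_copies.items()
                for a, v in arms.items()]
        pd.DataFrame(rows).to_csv(out / "truth_clones.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> pd.DataFrame:
    """Lay genes consecutively along arms: 0-based half-open, strictly
    increasing, non-overlapping; named marker/panel genes occupy the leading
    slots of their assigned arms, remaining genes get sequential ids."""
    config.validate()
    placement: dict[str, list[str]] = {}
    if config.named_gene_arms:
        for gene, arm in config.named_gene_arms.items():
            if arm not in config.arm_ids():
                raise ConfigurationError(f"named gene {gene}: arm {arm} not in table")
            placement.setdefault(arm, []).append(gene)

    rows = []
    counter = 0
    pos_by_chrom: dict[str, int] = {}
    for chrom, arm, n in config.arm_table:
        aid = arm_key(chrom, arm)
        named = placement.get(aid, [])
        if len(named) > n:
            raise ConfigurationError(f"arm {aid}: more named genes than slots")
        start = pos_by_chrom.get(chrom, 0)
        if chrom in pos_by_chrom:
            start += CENTROMERE_GAP
        for i in range(n):
            if i < len(named):
                gid = named[i]
            else:
                gid = f"G{counter:05d}"
                counter += 1
            g0 = start + i * GENE_STRIDE
            rows.append({"gene_id": gid, "chrom": chrom, "start": g0,
                         "end": g0 + GENE_LENGTH, "arm": arm})
        pos_by_chrom[chrom] = start + n * GENE_STRIDE
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _apportion(mixture: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n cells to the mixture simplex."""
    keys = sorted(mixture)
    raw = {k: mixture[k] * n for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    rest = n - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:rest]:
        counts[k] += 1
    return counts


def simulate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> SimulatedCohort:
    """Draw a full cohort (counts, truth annotation, bulk segments, survival)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    annotation = simulate_genome(config)
    gene_ids = annotation.index
    n_genes = len(gene_ids)
    arm_ids = config.arm_ids()
    gene_arm = np.array([arm_key(c, a) for c, a in
                         zip(annotation["chrom"], annotation["arm"])])

    named = config.named_genes()
    missing = [g for g in named if g not in gene_ids]
    if missing:
        raise ConfigurationError(f"marker/LR genes not in gene universe: {missing}")

    # baseline per-gene means: lognormal for bulk of genes, fixed low "off"
    # level for named marker/panel genes so programs control their state
    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, n_genes)
    named_pos = gene_ids.get_indexer(named)
    baseline[named_pos] = config.marker_off_mean
    baseline = pd.Series(baseline, index=gene_ids, name="baseline_mean")
    if config.gene_baseline:
        for g, v in config.gene_baseline.items():
            baseline.loc[g] = v

    # cell assignment
    cell_rows = []
    clone_copies_all: dict[str, dict[str, float]] = {}
    sector_mixtures: dict[tuple[str, str], dict[str, float]] = {}
    for patient in config.patient_ids():
        copies = config.clone_copies(patient)
        clone_copies_all.update(copies)
        for sector in config.sectors_for(patient):
            sector_mixtures[(patient, sector.name)] = dict(sector.mixture)
            counts = _apportion(sector.mixture, config.cells_per_sector)
            i = 0
            for key in sorted(counts):
                for _ in range(counts[key]):
                    is_clone = key in copies
                    cell_rows.append({
                        "cell_id": f"{patient}_{sector.name}_c{i:04d}",
                        "patient": patient,
                        "sector": f"{patient}_{sector.name}",
                        "sector_class": sector.sector_class,
                        "true_type": MALIGNANT_TYPE if is_clone else key,
                        "true_clone": key if is_clone else "CN-0",
                    })
                    i += 1
    cells = pd.DataFrame(cell_rows).set_index("cell_id")
    n_cells = len(cells)

    # expected-mean matrix: baseline x marker fold x dosage x library size
    mean = np.tile(baseline.values[:, None], (1, n_cells))

    def cells_for_key(key: str) -> np.ndarray:
        if key == MALIGNANT_TYPE:
            return (cells["true_type"] == MALIGNANT_TYPE).values
        sel = (cells["true_type"] == key).values
        sel |= (cells["true_clone"] == key).values
        return sel

    for key, programs in config.marker_program.items():
        col_sel = cells_for_key(key)
        if not col_sel.any():
            continue
        for genes, fold in programs:
            rows = gene_ids.get_indexer(list(genes))
            mean[np.ix_(rows, np.where(col_sel)[0])] *= fold
    for (lig, rec), (sender, receiver, fold) in config.lr_program.items():
        s_sel = np.where(cells_for_key(sender))[0]
        r_sel = np.where(cells_for_key(receiver))[0]
        if len(s_sel):
            mean[gene_ids.get_loc(lig), s_sel] *= fold
        if len(r_sel):
            mean[gene_ids.get_loc(rec), r_sel] *= fold

    # dosage: (copy/2) ** alpha on the clone's evented arms
    arm_index = {a: np.where(gene_arm == a)[0] for a in arm_ids}
    for clone, copies in clone_copies_all.items():
        col_sel = np.where((cells["true_clone"] == clone).values)[0]
        if len(col_sel) == 0:
            continue
        for a, copy in copies.items():
            if copy == 2.0:
                continue
            factor = (copy / 2.0) ** config.dose_exponent
            mean[np.ix_(arm_index[a], col_sel)] *= factor

    lib = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, n_cells)
    mean *= lib[None, :]

    # gamma-Poisson draw: var = m + dispersion * m^2
    phi = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    counts = rng.poisson(lam).astype(np.int32)
    matrix = ExpressionMatrix(sp.csr_matrix(counts), gene_ids, pd.Index(cells.index))

    # bulk segments: per-sector cell-weighted mean copy per arm
    arm_rows = annotation.copy()
    arm_rows["arm_id"] = gene_arm
    arm_bounds = {a: (arm_rows[arm_rows["arm_id"] == a]["start"].min(),
                      arm_rows[arm_rows["arm_id"] == a]["end"].max(),
                      arm_rows[arm_rows["arm_id"] == a]["chrom"].iloc[0])
                  for a in arm_ids}
    profiles = []
    for (patient, sector_name), _ in sector_mixtures.items():
        sample = f"{patient}_{sector_name}"
        block = cells[cells["sector"] == sample]
        seg_rows = []
        for a in arm_ids:
            cell_copy = np.array([
                clone_copies_all[cl].get(a, 2.0) if cl != "CN-0" else 2.0
                for cl in block["true_clone"]])
            start, end, chrom = arm_bounds[a]
            seg_rows.append({"chrom": chrom, "start": int(start), "end": int(end),
                             "copy": float(cell_copy.mean())})
        profiles.append(BulkCopyNumberProfile(
            sample=sample, patient=patient,
            segments=pd.DataFrame(seg_rows)))

    # survival: per-patient exponential with hazard scaled by the seeded
    # M2b/neutrophil burden (standardized across patients)
    burden = cells.groupby("patient")["true_type"].apply(
        lambda t: t.isin(SCORE_TYPES).mean())
    sd = burden.std(ddof=0)
    z = (burden - burden.mean()) / sd if sd > 0 else burden * 0.0
    survival = simulate_survival(z, config.hazard_ratio_per_score_unit,
                                 config.baseline_hazard, config.censor_horizon, rng)
    hazards = config.baseline_hazard * \
        config.hazard_ratio_per_score_unit ** z

    truth = GroundTruth(cells=cells, clone_copies=clone_copies_all,
                        sector_mixtures=sector_mixtures, baseline_means=baseline,
                        sample_scores=z, sample_hazards=hazards)
    return SimulatedCohort(matrix=matrix, annotation=cells.copy(),
                           bulk_profiles=profiles, survival=survival,
                           truth=truth, gene_annotation=annotation, config=config)


def simulate_survival(scores: pd.Series, hazard_ratio_per_score_unit: float,
                      baseline_hazard: float, censor_horizon: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential survival with administrative censoring at the horizon;
    hazard_i = baseline * hr ** score_i."""
    hazard = baseline_hazard * hazard_ratio_per_score_unit ** scores.values
    t = rng.exponential(1.0 / hazard)
    event = (t <= censor_horizon).astype(int)
    t = np.minimum(t, censor_horizon)
    return pd.DataFrame({"sample": scores.index, "time": t, "event": event})


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------

# relative gene-count weights of a human-like karyotype; acrocentric p arms
# (13/14/15/21/22p) carry no annotated genes, as in the real genome
_HG_WEIGHTS = {
    "chr1": (0.40, 2000), "chr2": (0.40, 1300), "chr3": (0.45, 1100),
    "chr4": (0.35, 800), "chr5": (0.35, 900), "chr6": (0.40, 1000),
    "chr7": (0.40, 950), "chr8": (0.35, 700), "chr9": (0.40, 800),
    "chr10": (0.35, 750), "chr11": (0.40, 1300), "chr12": (0.35, 1050),
    "chr13": (0.0, 350), "chr14": (0.0, 650), "chr15": (0.0, 650),
    "chr16": (0.40, 900), "chr17": (0.35, 1200), "chr18": (0.30, 300),
    "chr19": (0.40, 1450), "chr20": (0.40, 550), "chr21": (0.0, 250),
    "chr22": (0.0, 500),
}

MIN_GENES_PER_ARM = 5


def hg_like_arm_table(n_genes: int) -> list[tuple[str, str, int]]:
    """Distribute n_genes over 22 chromosomes x p/q with human-like weights;
    zero-weight arms (acrocentric p) are omitted."""
    raw = []
    for chrom, (p_frac, w) in _HG_WEIGHTS.items():
        if p_frac > 0:
            raw.append((chrom, "p", w * p_frac))
        raw.append((chrom, "q", w * (1 - p_frac)))
    total = sum(w for _, _, w in raw)
    scaled = [(c, a, n_genes * w / total) for c, a, w in raw]
    counts = [(c, a, max(MIN_GENES_PER_ARM, int(np.floor(x))))
              for (c, a, x) in scaled]
    diff = n_genes - sum(n for _, _, n in counts)
    frac_order = sorted(range(len(scaled)),
                        key=lambda i: -(scaled[i][2] - np.floor(scaled[i][2])))
    i = 0
    while diff != 0 and i < len(counts) * 4:
        j = frac_order[i % len(frac_order)]
        c, a, n = counts[j]
        if diff > 0:
            counts[j] = (c, a, n + 1)
            diff -= 1
        elif n > MIN_GENES_PER_ARM:
            counts[j] = (c, a, n - 1)
            diff += 1
        i += 1
    return counts


DEFAULT_MARKER_FOLD = 250.0
DEFAULT_LR_FOLD = 250.0


def default_marker_program() -> dict[str, list[tuple[tuple[str, ...], float]]]:
    f = DEFAULT_MARKER_FOLD
    return {
        MALIGNANT_TYPE: [(("PTPRZ1", "OLIG2", "AQP4", "SOX2"), f)],
        "normal-glia": [(("MOG", "MBP", "PLP1"), f)],
        "microglia": [(("P2RY12", "TMEM119"), f), (("PTPRC",), f)],
        "macrophage": [(("CD163", "CD14", "AIF1"), f), (("PTPRC",), f)],
        "M2b": [(("IL1RN", "VEGFA"), f), (("PTPRC",), f),
                (("CXCL1", "CXCL2", "CXCL3", "CXCL5", "CXCL6"), f / 2)],
        "lymphocyte": [(("CD2", "CD3D"), f), (("PTPRC",), f)],
        "neutrophil": [(("FCGR3B", "CSF3R", "S100A8", "S100A9"), f), (("PTPRC",), f)],
    }


def default_lr_program() -> dict[tuple[str, str], tuple[str, str, float]]:
    f = DEFAULT_LR_FOLD
    return {
        ("CX3CL1", "CX3CR1"): (MALIGNANT_TYPE, "microglia", f),
        ("CXCL8", "CXCR2"): ("M2b", "neutrophil", f),
        ("CXCL16", "CXCR6"): ("macrophage", "lymphocyte", f),
        ("CCL5", "CCR5"): ("lymphocyte", "macrophage", f),
    }


def _auto_named_gene_arms(arm_table: list[tuple[str, str, int]],
                          names: Sequence[str],
                          evented_chroms: Sequence[str]) -> dict[str, str]:
    """Round-robin named genes across quiet arms (not carrying clone events)
    so marker detection never confounds the dosage signal."""
    quiet = [arm_key(c, a) for c, a, n in arm_table
             if c not in evented_chroms and n >= 4]
    if not quiet:
        raise ConfigurationError("no quiet arm available for named genes")
    return {g: quiet[i % len(quiet)] for i, g in enumerate(names)}


def _named_genes_of(marker_program, lr_program) -> list[str]:
    tmp = SimulationConfig(arm_table=[("chr1", "p", 1)], sectors=[],
                           clone_tree_spec=[CloneSpec("x", None, frozenset())],
                           marker_program=marker_program, lr_program=lr_program,
                           n_patients=0)
    return tmp.named_genes()


def gs1_like_clone_tree() -> list[CloneSpec]:
    """Linear chain: root {chr7 amp, chr10 del} -> +{chr2 amp} -> +{chr5 del}."""
    return [
        CloneSpec("CN-A", None, frozenset({("chr7", "amp"), ("chr10", "del")})),
        CloneSpec("CN-B", "CN-A", frozenset({("chr2", "amp")})),
        CloneSpec("CN-C", "CN-B", frozenset({("chr5", "del")})),
    ]


def branched_clone_tree() -> list[CloneSpec]:
    """Branched: root {chr7 amp}; children add {chr2 amp} / {chr5 del}."""
    return [
        CloneSpec("CN-R", None, frozenset({("chr7", "amp")})),
        CloneSpec("CN-B1", "CN-R", frozenset({("chr2", "amp")})),
        CloneSpec("CN-B2", "CN-R", frozenset({("chr5", "del")})),
    ]


def _default_sectors() -> list[SectorSpec]:
    return [
        SectorSpec("core1", "tumoral", {
            "CN-A": 0.10, "CN-B": 0.15, "CN-C": 0.25, "macrophage": 0.20,
            "M2b": 0.06, "microglia": 0.06, "lymphocyte": 0.05,
            "neutrophil": 0.04, "normal-glia": 0.09}),
        SectorSpec("core2", "tumoral", {
            "CN-B": 0.20, "CN-C": 0.30, "macrophage": 0.22, "M2b": 0.05,
            "microglia": 0.08, "lymphocyte": 0.04, "neutrophil": 0.03,
            "normal-glia": 0.08}),
        SectorSpec("margin", "peritumoral", {
            "CN-C": 0.15, "microglia": 0.30, "macrophage": 0.10,
            "normal-glia": 0.30, "lymphocyte": 0.08, "neutrophil": 0.03,
            "M2b": 0.04}),
        SectorSpec("adjacent", "adjacent", {
            "normal-glia": 0.60, "microglia": 0.25, "lymphocyte": 0.10,
            "macrophage": 0.05}),
    ]


def default_config(seed: int = 0, n_patients: int = 4,
                   cells_per_sector: int = 55,
                   n_genes: int = 1200) -> SimulationConfig:
    """The package's default multi-sector cohort: a GS1-like linear clone
    chain shared by all patients, macrophage-rich cores, microglia-rich
    margins, seeded chemokine programs."""
    arm_table = hg_like_arm_table(n_genes)
    marker = default_marker_program()
    lr = default_lr_program()
    names = _named_genes_of(marker, lr)
    return SimulationConfig(
        arm_table=arm_table,
        clone_tree_spec=gs1_like_clone_tree(),
        sectors=_default_sectors(),
        n_patients=n_patients,
        cells_per_sector=cells_per_sector,
        marker_program=marker,
        lr_program=lr,
        named_gene_arms=_auto_named_gene_arms(
            arm_table, names, ("chr2", "chr5", "chr7", "chr10")),
        seed=seed,
    )


def gs1_like_config(seed: int = 0, n_cells: int = 2000,
                    n_genes: int = 5000) -> SimulationConfig:
    """Single-patient dose-recovery cohort at a configurable scale."""
    cfg = default_config(seed=seed, n_patients=1,
                         cells_per_sector=n_cells // 4, n_genes=n_genes)
    return cfg


def branched_config(seed: int = 0, n_cells: int = 600,
                    n_genes: int = 2000) -> SimulationConfig:
    """Single-patient cohort seeded with the branched clone tree."""
    arm_table = hg_like_arm_table(n_genes)
    marker = default_marker_program()
    names = _named_genes_of(marker, {})
    sectors = [
        SectorSpec("core", "tumoral", {
            "CN-R": 0.20, "CN-B1": 0.20, "CN-B2": 0.20, "macrophage": 0.15,
            "microglia": 0.10, "normal-glia": 0.15}),
        SectorSpec("margin", "peritumoral", {
            "CN-B2": 0.15, "microglia": 0.30, "normal-glia": 0.40,
            "macrophage": 0.15}),
    ]
    return SimulationConfig(
        arm_table=arm_table, clone_tree_spec=branched_clone_tree(),
        sectors=sectors, n_patients=1, cells_per_sector=n_cells // 2,
        marker_program=marker,
        named_gene_arms=_auto_named_gene_arms(
            arm_table, names, ("chr2", "chr5", "chr7")),
        seed=seed,
    )


def crosstalk_config(seed: int = 0, cells_per_sector: int = 300,
                     n_genes: int = 1200) -> SimulationConfig:
    """Single-patient cohort with balanced cell types (>= ~45 cells/type) so
    ligand-receptor detection fractions are estimated stably."""
    arm_table = hg_like_arm_table(n_genes)
    marker = default_marker_program()
    lr = default_lr_program()
    names = _named_genes_of(marker, lr)
    mix_core = {"CN-A": 0.12, "CN-B": 0.04, "CN-C": 0.04, "microglia": 0.16,
                "macrophage": 0.16, "M2b": 0.16, "lymphocyte": 0.16,
                "neutrophil": 0.16}
    mix_margin = {"CN-C": 0.10, "microglia": 0.22, "macrophage": 0.17,
                  "M2b": 0.17, "lymphocyte": 0.17, "neutrophil": 0.17}
    sectors = [SectorSpec("core", "tumoral", mix_core),
               SectorSpec("margin", "peritumoral", mix_margin)]
    return SimulationConfig(
        arm_table=arm_table, clone_tree_spec=gs1_like_clone_tree(),
        sectors=sectors, n_patients=1, cells_per_sector=cells_per_sector,
        marker_program=marker, lr_program=lr,
        named_gene_arms=_auto_named_gene_arms(
            arm_table, names, ("chr2", "chr5", "chr7", "chr10")),
        seed=seed,
    )


def deconfound_config(seed: int = 0, cells_per_sector: int = 60,
                      n_genes: int = 1500) -> SimulationConfig:
    """Four patients carrying different combinations of the same recurrent
    arm events (each event abnormal in 3 patients, hence masked by the
    stable-region criterion); the shared malignant expression program should
    mix across patients only after masking."""
    arm_table = hg_like_arm_table(n_genes)
    marker = default_marker_program()
    names = _named_genes_of(marker, {})
    combos = {
        "P1": frozenset({("chr7", "amp"), ("chr10", "del")}),
        "P2": frozenset({("chr7", "amp"), ("chr2", "amp")}),
        "P3": frozenset({("chr10", "del"), ("chr2", "amp")}),
        "P4": frozenset({("chr7", "amp"), ("chr10", "del"), ("chr2", "amp")}),
    }
    clone_spec = {p: [CloneSpec(f"T-{p}", None, ev)] for p, ev in combos.items()}
    sectors = {
        p: [
            SectorSpec("core", "tumoral", {
                f"T-{p}": 0.50, "macrophage": 0.20, "microglia": 0.10,
                "normal-glia": 0.20}),
            SectorSpec("margin", "peritumoral", {
                f"T-{p}": 0.20, "microglia": 0.30, "macrophage": 0.10,
                "normal-glia": 0.40}),
        ]
        for p in combos
    }
    return SimulationConfig(
        arm_table=arm_table, clone_tree_spec=clone_spec, sectors=sectors,
        n_patients=4, cells_per_sector=cells_per_sector,
        marker_program=marker,
        named_gene_arms=_auto_named_gene_arms(
            arm_table, names, ("chr2", "chr7", "chr10")),
        seed=seed,
    )
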