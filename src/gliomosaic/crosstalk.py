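"""Chemokine ligand-receptor co-detection map, gene-signature enrichment
scoring and score-based survival stratification.

The interaction map is deliberately simple: an edge (ligand, receptor,
sender type, receiver type) is active when the ligand is detected in at
least ``min_fraction`` of sender cells and the receptor in at least
``min_fraction`` of receiver cells.  Detection means a positive
log-normalized value.  The M2b-macrophage/neutrophil burden of a sample is
summarized by the mean of gene-wise z-scored log expression over a signature
gene set; samples are split at the score median (or into tertile extremes)
and compared by the two-group log-rank test with Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import rankdata

from .errors import ConfigurationError, FormatError
from .io_qc import ExpressionMatrix

log = logging.getLogger(__name__)


def load_lr_pairs(path: str | Path | None = None) -> pd.DataFrame:
    """Ligand-receptor pair table (ligand, receptor, family); defaults to the
    shipped chemokine panel."""
    if path is None:
        ref = importlib_resources.files("gliomosaic.resources") / "chemokine_pairs.tsv"
        with importlib_resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if df.duplicated(subset=["ligand", "receptor"]).any():
        dup = df[df.duplicated(subset=["ligand", "receptor"])].iloc[0]
        raise FormatError(f"duplicate ligand-receptor pair: {dup['ligand']}-{dup['receptor']}")
    if (df["ligand"].astype(str).str.len() == 0).any() or \
       (df["receptor"].astype(str).str.len() == 0).any():
        raise FormatError("empty gene name in pair table")
    return df


def ligand_receptor_map(matrix: ExpressionMatrix, annotation_table: pd.DataFrame,
                        pairs: pd.DataFrame | None = None,
                        min_fraction: float = 0.1,
                        type_col: str = "cell_type") -> pd.DataFrame:
    """Co-detection edges over all (pair, sender type, receiver type) combos.

    Returns the full edge table with detection fractions, mean lognorm and
    the ``active`` flag; pairs with genes absent from the matrix are skipped
    with a warning (chemokine panels routinely exceed any one matrix).
    """
    if pairs is None:
        pairs = load_lr_pairs()
    ann = annotation_table.set_index("cell_id") if "cell_id" in annotation_table.columns \
        else annotation_table
    ann = ann.loc[matrix.cell_ids]
    types = ann[type_col]
    type_names = list(pd.unique(types))
    if len(type_names) < 2:
        raise ConfigurationError("need >= 2 cell types for an interaction map")
    lognorm = matrix.require_lognorm()
    members = {t: np.where(types.values == t)[0] for t in type_names}

    def stats(gene: str) -> dict[str, tuple[float, float]]:
        row = lognorm[matrix.gene_ids.get_loc(gene)]
        out = {}
        for t, idx in members.items():
            vals = row[idx]
            out[t] = (float((vals > 0).mean()), float(vals.mean()))
        return out

    rows = []
    for _, pair in pairs.iterrows():
        lig, rec = str(pair["ligand"]), str(pair["receptor"])
        if lig not in matrix.gene_ids or rec not in matrix.gene_ids:
            log.warning("pair %s-%s skipped: gene absent from matrix", lig, rec)
            continue
        lig_stats, rec_stats = stats(lig), stats(rec)
        for sender in type_names:
            for receiver in type_names:
                sf, sm = lig_stats[sender]
                rf, rm = rec_stats[receiver]
                rows.append({
                    "ligand": lig, "receptor": rec,
                    "family": pair.get("family", ""),
                    "sender": sender, "receiver": receiver,
                    "sender_fraction": sf, "receiver_fraction": rf,
                    "sender_mean": sm, "receiver_mean": rm,
                    "active": sf >= min_fraction and rf >= min_fraction,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signature scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreResult:
    scores: pd.Series
    missing_genes: list[str]
    zero_variance_genes: list[str]


def load_m2bneu_genes(path: str | Path | None = None) -> list[str]:
    """Signature gene list, one id per line; defaults to the shipped placeholder
    M2b/neutrophil panel (a synthetic stand-in, not the published 38-gene list)."""
    if path is None:
        ref = importlib_resources.files("gliomosaic.resources") / "m2bneu_genes.tsv"
        with importlib_resources.as_file(ref) as p:
            lines = p.read_text().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def signature_score(expression: ExpressionMatrix | pd.DataFrame,
                    gene_set: Sequence[str],
                    method: str = "zmean") -> ScoreResult:
    """Per-cell (or per-sample) enrichment score of a gene set.

    ``zmean``: mean over present genes of gene-wise z-scored log expression.
    ``rank``: mean per-column rank percentile of the set's genes (robust
    alternative).  Bulk input is a genes x samples DataFrame of log expression.
    """
    if isinstance(expression, ExpressionMatrix):
        values = pd.DataFrame(expression.require_lognorm(),
                              index=expression.gene_ids,
                              columns=expression.cell_ids)
    else:
        values = expression
    if values.shape[1] < 2:
        raise ConfigurationError("scoring needs >= 2 samples/cells")
    present = [g for g in gene_set if g in values.index]
    missing = [g for g in gene_set if g not in values.index]
    if not present:
        raise ConfigurationError("no signature gene present in the expression input")
    if missing:
        log.warning("signature genes missing from input: %s", missing)

    sub = values.loc[present]
    if method == "zmean":
        sd = sub.std(axis=1, ddof=0)
        zero_var = list(sub.index[sd == 0])
        if zero_var:
            log.warning("zero-variance genes excluded from z-scoring: %s", zero_var)
        keep = sub.index[sd > 0]
        if len(keep) == 0:
            # fully flat input carries no enrichment signal anywhere
            scores = pd.Series(0.0, index=sub.columns)
        else:
            z = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0) \
                             .div(sd.loc[keep], axis=0)
            scores = z.mean(axis=0)
    elif method == "rank":
        zero_var = []
        pct = values.rank(axis=0, method="average") / len(values.index)
        scores = pct.loc[present].mean(axis=0)
    else:
        raise ConfigurationError(f"unknown scoring method {method!r}")
    scores.name = "score"
    return ScoreResult(scores=scores, missing_genes=missing,
                       zero_variance_genes=zero_var)


# ---------------------------------------------------------------------------
# Survival stratification
# ---------------------------------------------------------------------------

@dataclass
class StratifyResult:
    groups: pd.Series                     # "high"/"low" per sample
    statistic: float                      # log-rank chi-square
    p_value: float
    km_tables: dict[str, pd.DataFrame]    # per group: time, at_risk, events, survival


def survival_stratify(scores: pd.Series, survival: pd.DataFrame,
                      cut: str = "median") -> StratifyResult:
    """Split samples by score and compare survival with the log-rank test.

    *survival* needs columns sample, time, event (event=1 observed death).
    ``cut="median"``: above-median vs rest; ``cut="tertile-extremes"``: top vs
    bottom tertile, middle third excluded.
    """
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    common = scores.index.intersection(surv.index)
    missing = scores.index.difference(surv.index)
    if len(missing):
        raise ConfigurationError(f"scored samples without survival: {list(missing[:3])}")
    surv = surv.loc[common]
    s = scores.loc[common]
    if (surv["time"] <= 0).any():
        raise ConfigurationError("survival times must be > 0")
    if surv["event"].sum() == 0:
        raise ConfigurationError("log-rank undefined: all samples censored")

    if cut == "median":
        med = s.median()
        groups = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")
    elif cut == "tertile-extremes":
        lo_q, hi_q = s.quantile([1 / 3, 2 / 3])
        groups = pd.Series(np.nan, index=s.index, dtype=object, name="group")
        groups[s <= lo_q] = "low"
        groups[s >= hi_q] = "high"
        groups = groups.dropna()
        surv = surv.loc[groups.index]
    else:
        raise ConfigurationError(f"unknown cut {cut!r}")
    if groups.nunique() < 2:
        raise ConfigurationError("score split produced a single group")

    hi = groups.index[groups == "high"]
    lo = groups.index[groups == "low"]
    res = logrank_test(surv.loc[hi, "time"], surv.loc[lo, "time"],
                       event_observed_A=surv.loc[hi, "event"],
                       event_observed_B=surv.loc[lo, "event"])

    km_tables = {}
    for name, idx in (("high", hi), ("low", lo)):
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[idx, "time"], surv.loc[idx, "event"], label=name)
        tbl = kmf.event_table
        sf = kmf.survival_function_[name]
        km_tables[name] = pd.DataFrame({
            "time": tbl.index.values,
            "at_risk": tbl["at_risk"].values,
            "events": tbl["observed"].values,
            "survival": sf.reindex(tbl.index).values,
        })
    return StratifyResult(groups=groups, statistic=float(res.test_statistic),
                          p_value=float(res.p_value), km_tables=km_tables)
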