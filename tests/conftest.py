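import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from gliomosaic.io_qc import ExpressionMatrix, normalize
from gliomosaic.synthdata import default_config, simulate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_matrix(counts, gene_ids=None, cell_ids=None, normalized=True,
                scale=100_000) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a dense array (genes x cells)."""
    counts = np.asarray(counts)
    genes = gene_ids if gene_ids is not None else [f"g{i}" for i in range(counts.shape[0])]
    cells = cell_ids if cell_ids is not None else [f"c{j}" for j in range(counts.shape[1])]
    m = ExpressionMatrix(sp.csr_matrix(counts), pd.Index(genes), pd.Index(cells))
    if normalized:
        normalize(m, scale=scale)
    return m


def lognorm_matrix(values, gene_ids=None, cell_ids=None) -> ExpressionMatrix:
    """Matrix whose normalized layer is set directly to *values* (genes x cells)."""
    values = np.asarray(values, dtype=float)
    m = make_matrix(np.ones_like(values, dtype=int), gene_ids, cell_ids,
                    normalized=False)
    m.lognorm = values
    return m


@pytest.fixture(scope="session")
def small_cohort():
    """Two-patient default cohort shared by read-only tests."""
    cohort = simulate_cohort(default_config(seed=11, n_patients=2,
                                            cells_per_sector=60, n_genes=900))
    normalize(cohort.matrix)
    return cohort


@pytest.fixture(scope="session")
def dose_cohort():
    """Full-scale dose-recovery cohort (2000 cells x 5000 genes, GS1-like
    linear clone chain) with its inferred arm scores; shared by the CNV
    property tests and the acceptance suite."""
    from gliomosaic.cnv import CNVParams, infer_cnv, summarize_arms
    from gliomosaic.synthdata import gs1_like_config

    cohort = simulate_cohort(gs1_like_config(seed=101, n_cells=2000,
                                             n_genes=5000))
    normalize(cohort.matrix)
    arm = summarize_arms(
        infer_cnv(cohort.matrix, cohort.gene_annotation, CNVParams()),
        cohort.gene_annotation)
    return cohort, arm
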