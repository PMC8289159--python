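# Methods

`gliomosaic` re-implements, as a tested pipeline, the analysis style used in
multi-sector glioma single-cell RNA-seq studies: copy-number profiles are
inferred from expression alone, malignant cells are grouped into arm-level
CNV subclones whose order of accumulation is reconstructed, clustering is
de-confounded by masking genes in copy-number-variable genomic regions,
tumor and microenvironment cells are annotated by marker gates and signature
averaging, chemokine ligand–receptor cross-talk is mapped by co-detection,
and an M2b-macrophage/neutrophil enrichment score stratifies survival.
Because the deposited patient data are not part of this package, a fully
specified synthetic-cohort generator provides ground truth for every stage;
all quantitative claims made by the tests are parameter-recovery results on
that generator.

## Expression-inferred CNV

For cell $c$ and gene $g$ (genome-ordered), the relative expression is

    r[c,g] = x[c,g] − mean over reference cells of x[·,g]

where `x` is `log(1 + s·count/total)` with scale `s = 1e5` (natural log).
The reference set is either user-supplied or "auto": cells detecting an
immune (`PTPRC`) or normal-glia (`MOG`) marker, gated on the normalized
layer only so the choice cannot depend on CNV output. The profile is then

1. capped per gene at ±`gene_clip` (default 1.5). A single strongly
   cell-type-specific gene shifts by 3+ natural-log units and would
   otherwise masquerade as a focal event; dosage-level shifts
   (log 1.5 ≈ 0.41 for a single-copy gain, log 0.5 ≈ −0.69 for a loss) pass
   unchanged. A tighter cap (e.g. 0.5) measurably truncates genuine dose
   signal because per-gene noise is asymmetric around it.
2. smoothed by a centered moving average of `window` genes (default 101,
   truncated at block edges). Smoothing blocks are chromosome **arms**: the
   centromere is a boundary because arm-level events are the unit of the
   downstream clonal analysis.
3. re-centered by each cell's median score (guards against library-size
   residue), and clipped to ±`clip` (default 0.5).

Arm scores are per-cell means of the smoothed profile over each arm. Arms
with fewer than `min_genes_per_arm` (default 25) scored genes are dropped: a
handful of genes cannot support an arm-level call, and the selected
fluctuations of tiny arms otherwise surface as spurious subclonal events.
Arm scores increase monotonically with log2(copy/2); they are attenuated
relative to it (smoothing, clipping, dropout), so all discretization uses
the configurable thresholds below rather than theoretical dosage values.

**CNV subgroups and malignancy.** Cells are grouped by Ward/Euclidean
hierarchical clustering of arm scores; `k` is explicit or chosen in [2, 8]
by mean silhouette. Clustering routinely splits CNV-equivalent diploid cells
by expression program (immune vs glia) — as observed in real cohorts — so
CNV *subtypes* are obtained by merging clusters whose consensus event sets
coincide. A subgroup is non-malignant when its mean arm score stays below
`amp_threshold` (default 0.1) in magnitude on every arm; cells inherit their
subgroup's call.

## Subclones and clonal ordering

Malignant cells are re-clustered (Ward/Euclidean) into clones CN-1..CN-k,
labelled by increasing consensus event count; diploid cells are CN-0. Per
clone and arm, the consensus state is amp when the mean arm score ≥
`amp_threshold` (inclusive), del when ≤ `del_threshold` (−0.1), else
neutral. Under the assumption that arm-level events are not lost once
acquired, clone A is ancestral to B when A's event set is a strict subset of
B's. The clone graph is the transitive reduction of this containment order;
identical event sets merge with a warning; a "diamond" (one clone containing
two incomparable smaller clones) keeps the parent with the most shared
events so the output is always a tree; clones with no observed ancestor hang
under the observed clone carrying the intersection of their events, or under
a synthetic unobserved-ancestor node holding that intersection when no
observed clone does. For recovery experiments `k` is fixed to the seeded
clone count, mirroring the practice of cutting the dendrogram at the number
of visually distinct groups: silhouette tends to merge the two smallest
clones, and deliberate over-segmentation invents borderline events on
mid-size arms.

Differential expression between clone groups uses the two-sided Wilcoxon
rank-sum test per gene on normalized expression with Benjamini–Hochberg
adjustment; genes on arms whose consensus copy state differs between the
groups carry a `cnv_dose` flag so dosage-driven changes are distinguishable
from program changes.

## Stable-region mask and embedding

Bulk copy-number segments (per biopsy sample) assign each gene a copy number
(uncovered positions count as diploid 2.0; a gene straddling two segments
takes the larger overlap). A gene is *abnormal* in a patient when any of the
patient's samples gives it copy ≤ 1.8 or ≥ 2.2 — the stable interval is open
at both ends — and it is retained for clustering when at most
`max_abnormal_patients` (default 2) patients are abnormal. Masking is per
gene; patient-level abnormality aggregates over that patient's biopsies.

Embedding: highly variable genes (Seurat-flavor dispersion) are selected
among retained genes only; PCA (arpack) on scaled expression; kNN graph;
Leiden community detection at the configured resolution (clusters never come
from 2-D coordinates); t-SNE from the same principal components for display.
De-confounding is quantified by the mean per-cell entropy of patient labels
among same-cell-type kNN neighbors in PCA space, normalized per type by
log(#patients carrying the type); the mask should raise it when
patient-specific CNV dosage is the confounder.

## Annotation

Marker gates are evaluated in order; the first gate whose conditions hold
(any required marker detected, no forbidden marker detected, malignancy
requirement satisfied) wins. Detection means normalized expression above a
threshold (default 0: any count). The coarse default order is metastasis
(`KRT5+`, malignant), immune (`PTPRC+`), normal glia (`MOG+`, `PTPRC−`),
ciliated tumor (`HYDIN+`, malignant), glioma (any of
`PTPRZ1`/`OLIG2`/`AQP4`, malignant), else unassigned. `MKI67` detection sets
an independent proliferation flag. An extended gate set resolves fine immune
types (M2b by `IL1RN`, microglia by `P2RY12`/`TMEM119`, macrophage by
`CD163`, lymphocyte by `CD2`/`CD3D`, neutrophil by `FCGR3B`/`CSF3R`) before
the coarse immune gate; the pipeline uses it so the cross-talk map can
distinguish sender/receiver populations. Gating is per cell; a
majority-vote-per-cluster smoothing is available.

Subtype classification scores each cell on each signature as the mean of
gene-wise z-scored normalized expression over the signature's genes; the
argmax wins, exact ties are labelled "ambiguous", and the margin (top minus
second) is reported. Non-malignant cells get a null subtype. The shipped
signature lists (and the 38-gene M2b/neutrophil panel) are clearly labelled
illustrative placeholders — the authoritative lists live outside this
package — and every test uses synthetic signatures, so no result depends on
the shipped files.

## Cross-talk and survival

An interaction edge (ligand, receptor, sender type, receiver type) is active
when the ligand is detected (normalized value > 0) in ≥ `min_fraction`
(default 0.1) of sender cells and the receptor likewise in receiver cells.
The full combinatorial table is returned with fractions and means; pairs
with genes absent from the matrix are skipped with a warning.

The enrichment score of a gene set is the mean over its present genes of
gene-wise z-scored log expression (zero-variance genes excluded with a
warning; a fully flat input scores 0 everywhere); a rank-percentile variant
is available for robustness comparisons. Samples are split at the score
median (or into tertile extremes) and compared with the standard two-group
log-rank test; Kaplan–Meier tables (time, at-risk, events, survival) are
emitted per group. The test statistic is validated in the suite against a
hand-computed 6-sample worked example (chi-square 529/1091).

## Synthetic cohorts

Counts are gamma–Poisson: gene g in cell c has mean
`baseline[g] · marker_fold · (copy/2)^α · libsize[c]` and variance
`m + φ·m²` with shared dispersion φ (default 0.3). Defaults and what they
emulate:

- `baseline_meanlog 0.5, baseline_sdlog 1.0` (lognormal per-gene means) —
  deep full-length scRNA-seq; at 5,000 genes this yields ≈ 3,500–4,000
  detected genes per cell, matching high-sensitivity plate-based platforms.
- `libsize_meanlog 0, libsize_sdlog 0.25` — moderate depth variation.
- dose exponent α (default 1.0) — multiplicative dosage; amp copy 3, del
  copy 1 applied to all arms of the evented chromosome.
- marker programs — named marker genes are near-silent off-type
  (`marker_off_mean 0.02`) and boosted ~250× on-type; ligand/receptor
  programs boost the ligand in the sender type and the receptor in the
  receiver type. Named genes are placed on "quiet" arms that carry no clone
  events, so marker detection never confounds dosage.
- genomes are human-like: 22 chromosomes with realistic relative arm sizes;
  acrocentric p arms (13/14/15/21/22p) carry no genes, as in the real genome.
- sector mixtures are exact (largest-remainder apportionment), with
  macrophage-rich tumoral cores and microglia-rich peritumoral margins;
  bulk segments are the cell-weighted mean copy per arm, keeping bulk and
  single-cell truth consistent by construction.
- survival is exponential per patient with administrative censoring at a
  horizon (default 60 months); the hazard scales as `hr^z` (default hr 2.0)
  where z is the patient's standardized seeded M2b+neutrophil fraction.

What the generator does **not** emulate: doublets, ambient RNA, batch
chemistry effects, focal (sub-arm) CNVs, allelic effects, transcriptional
bursting beyond NB dispersion, spatial coordinates beyond a sector label,
and continuous differentiation gradients. Passing tests therefore
demonstrate correctness of the algorithms under a clean generative model,
not performance on real tissue.

## Numerical choices and degenerate inputs

- QC removes failing cells first, then genes detected in too few surviving
  cells; an all-removed outcome is an explicit error. The operation is
  idempotent on data with threshold margin; a pathological matrix could in
  principle change cell metrics after gene removal.
- Normalization refuses zero-total cells (an invariant violation — QC with
  `min_counts_per_cell ≥ 1` removes them).
- Chromosome arms shorter than the smoothing window use the largest odd
  width that fits; even windows are rejected at configuration time.
- Consensus thresholds are inclusive (score exactly at `amp_threshold` is
  amp). Root ties in the clone tree break lexicographically.
- All-identical arm profiles degenerate to a single cluster with a warning
  instead of a silhouette failure.
- Argmax ties in subtype classification are "ambiguous", never arbitrary.
- The pipeline fans a single global seed out to per-stage seeds by fixed
  offsets, so resumed stages reproduce the original run; manifests record
  the seed, an analysis-parameter hash (paths excluded) and output
  checksums, and contain no timestamps.

## Problem sizes used by the test and acceptance workloads

Recovery experiments run at 2,000 cells × 5,000 genes for dose/clone-tree
recovery (the smallest seeded clone then has ≥ 50 cells, which the
hierarchical clustering needs to avoid selection-noise events), 480 cells ×
1,500 genes per seed for the de-confounding entropy comparison, 2,000+
cells for subtype recovery, 100–200 cells per group for differential
expression calibration, and 200 samples × 100 replicates for log-rank
power. These sizes were chosen as the smallest at which the corresponding
estimators are stable.

## Known limitations

- Arm scores are attenuated, nonlinear functions of true dosage; thresholds
  are calibrated to the generator's noise, and real data may need different
  values (all are configurable).
- Silhouette-based `k` selection prefers merging small clones; explicit `k`
  is recommended when the clone count is known or visually evident.
- The clonal ordering assumes no event loss and no convergent (parallel)
  acquisition of the same arm event; violations surface as merged clones or
  synthetic ancestors.
- The cross-talk map is co-detection only; it does not test statistical
  enrichment of edges against a permutation null.
- The log-rank comparison is two-group only.
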