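# Methods

This note documents the models, parameter choices, and numerical
conventions behind `limbatlas`, and what the synthetic study conditions do
and do not establish about real data.

## Synthetic data model

Counts are negative binomial via a gamma-Poisson mixture: for cell *i* and
gene *j*, `count ~ Poisson(Gamma(1/d, mu_ij * d))`, with dispersion
`d = nb_dispersion = 0.3` (droplet-typical overdispersion; the NB mean is
preserved exactly). Log-scale structure enters the mean matrix additively:

- a per-gene baseline drawn once per configuration (`N(0, 1)` in natural
  log), shared by all species and types, so species differ only through the
  planted features — the generator deliberately has no further batch
  effect;
- type identity: each non-AER type over-expresses its own 40-gene marker
  block by `marker_effect = 2.0` (natural log, ~7.4-fold);
- the AER program: 100 genes over-expressed by `aer_effect = 2.0` in AER
  cells; the AEC (wound epithelium) expresses only the first
  `aec_overlap = 0.6` fraction of those genes, emulating a partial
  re-deployment (e.g. missing FGF-pathway ligands), plus its own marker
  block;
- the regenerating CT program: exactly `round(ct_program_fraction * n_CT)`
  CT cells additionally over-express the AEC-shared portion of the program
  (`ct_program_size = 60` genes). The planted subset coincides with the
  program portion the wound epithelium runs because the phenomenon being
  emulated is mesodermal cells *co-aggregating with* the AEC; a subset
  private to CT would instead create a third, separate population;
- the cell-cycle confound: 50 cycle genes shifted by
  `cycle_strength = 2.0` in a `cycling_fraction = 0.2` subset of cells.
  Cycle genes carry a −2 baseline shift so that their induction occupies a
  few percent of a cycling cell's library, as real S/G2M signatures do. A
  neutral baseline would make the induced set ~20% of the library, and the
  resulting depth-normalization composition shift cannot be removed by any
  gene-exclusion correction;
- library size: a per-cell log-normal factor (sigma = 0.3, unit mean)
  scales each cell's expected total to `depth_mean = 3000`, making
  normalization non-trivial while keeping the mean depth on target;
- orthology structure: the homeolog species emits `SYM.L`/`SYM.S` row pairs
  splitting a gene's mean 0.7/0.3 (so the max-total collapse rule has a
  deterministic right answer), and every species carries 50 private
  symbols absent elsewhere (so one-to-one intersection is exercised:
  1200 → 1150 genes by construction).

Spatial sections place three contiguous domains along the proximo-distal
axis of a spot grid — intact CT, blastema (60% program-carrying CT), and a
distal AEC rim — and each spot sums the counts of 10 sampled single cells
from its domain mixture, a realistic Visium spot occupancy.

What the generator does **not** model: doublets, ambient RNA, batch
effects beyond species identity, gene-length or GC biases, and real
cross-species divergence of expression levels (orthologous genes share
baselines here). Passing tests therefore demonstrate that each algorithm
recovers the structure it targets under honest droplet-like noise — not
that real atlases integrate this cleanly.

## Preprocessing conventions

Normalization is depth scaling to 10,000 counts per cell followed by
log1p. HVGs are ranked by standardized variance: per-gene raw-count
z-scores under a mean-variance trend, clipped at sqrt(n_cells), and the
variance of the clipped scores ranks the genes. The trend is a degree-2
polynomial of log10(variance) on log10(mean) — a smooth-fit stand-in with
the same role as a local regression. The scaled layer is the per-gene
z-score of normalized values clipped at ±10 (the usual convention). PCA is
an exact SVD of the centered scaled matrix; loading columns are unit-norm
with the largest-magnitude entry positive, a deterministic sign convention.

Cell-cycle scores are means of set genes minus means of a seeded control
pool drawn from 25 mean-expression bins (25 controls per set gene); the
phase call is "S" if S > G2M and S > 0, "G2M" if G2M ≥ S and G2M > 0, else
"G1". Cycle-correlated components are flagged when the summed |loading| of
cycle genes exceeds a dataset-specific threshold; the expected sum for a
cycle-free component is `n_cycle_genes * sqrt(2/pi) / sqrt(n_genes_used)`
(~1.2 for 50 cycle genes among 1150), so the working threshold on the
synthetic panel is 3, which sits far above that baseline and far below the
~5–6 of a genuine cycle component. "Top 10%" of genes is computed per
flagged component (ceil) and the union is removed once.

Clustering is Louvain (igraph multilevel) on an unweighted union kNN
graph of PC scores, seeded. Per-dataset defaults are 15 PCs, k = 20,
resolution 1.0; the atlas workflow clusters the joint embedding with
k = 30 and resolution 0.5, a coarser granularity appropriate for
recovering cell types from a pooled multi-dataset graph rather than
within-type substructure. UMAP is reporting-only; nothing downstream
consumes the 2-D coordinates.

Cluster downsampling halves clusters above the cap (default 500):
`n → ceil(n/2)`, sampled without replacement, seeded.

## Integration

Integration features are ranked by (number of datasets calling the gene
variable, mean within-dataset HVG rank, lexicographic id). The MNN
reference implementation z-scales features per dataset, runs a joint PCA,
and merges datasets largest-first: mutual nearest neighbors (k = 20)
between the merged set and the incoming dataset are anchors, and each
incoming cell is shifted by a Gaussian-kernel-weighted mean of anchor
displacement vectors. The kernel bandwidth is per-cell: the distance to the
k-th nearest anchor, so each correction averages over roughly one anchor
neighborhood; a hyper-local bandwidth would re-introduce neighbor-level
noise, and a global one could not adapt to type-specific shifts. A dataset
with no mutual pairs is appended uncorrected with a warning. The confusion
matrix of the integration-accuracy diagnostic is normalized per integrated
cluster (column maxima = 1).

## Neighbor-voting AUROC

Cells are connected by Spearman correlation over the feature matrix
(Pearson on within-cell feature ranks; a constant cell's undefined
correlations are set to 0). Each cell's correlation vector is
rank-standardized to [0, 1] with self excluded. For an ordered cluster
pair (A in dataset 1, B in dataset 2), each dataset-2 cell's vote is its
mean standardized connectivity to A's cells, and the AUROC is the mid-rank
Mann-Whitney probability that B's cells out-vote the other dataset-2
cells. The reported score averages both directions; pairs where either
direction lacks negatives (a single-cluster dataset) are missing (NaN),
distinct from 0. Scores are invariant to monotone feature transforms.

## Per-cell gene-set AUC

Genes are ranked per cell by decreasing raw count, ties resolved by the
fixed gene order (stable sort — deterministic, unlike randomized tie
breaking). With T = ceil(top_fraction × n_genes), the score is the sum of
the member-recovery curve over ranks 1..T divided by its attainable
maximum (all members packed at the top ranks). `top_fraction` defaults to
0.05, the conventional top-ranking window. Raw counts, not normalized
values, are ranked: the statistic depends only on the within-cell ordering.

## Differential expression and programs

`wilcoxon_deg` uses the mid-rank U statistic with normal approximation,
tie and continuity corrections (group sizes in practice are ~150+, where
the approximation is excellent; on distinct-valued toys with ≥3 cells per
group it stays within 0.04 of exact enumeration). BH adjusts across all
tested genes. Log fold change is log2((mean_A + 1)/(mean_B + 1)) on
normalized values. Marker intersection keeps genes significantly up
(adjusted p < 0.05, positive fold change) in every comparison, ordered by
minimum fold change.

Consensus NMF: `n_restarts` seeded NMF runs (multiplicative updates),
spectra unit-L2-normalized and pooled; spectra whose mean distance to
their 3 nearest pooled neighbors exceeds the 90th percentile are dropped;
k-means (seeded) clusters the rest into k groups; consensus spectra are
per-cluster medians, re-normalized; usages are refit by NNLS per cell;
error is the Frobenius reconstruction error and stability the mean
silhouette of the spectra clustering. The selected k minimizes error among
k whose stability is at least 80% of the best — "specifically high
stability with lowest error" made into a rule. Module specificity: a
module is target-specific when its mean usage in the target cluster is at
least 2× the maximum mean usage over every other cluster; both the 80%
stability fraction and the 2× fold are explicit package decisions where
the underlying judgement is usually visual.

Gene-set projection subsets cells to the requested clusters, takes each
set's top 500 genes present (ranked by supplied weights — fold changes or
module loadings — otherwise set order), z-scales the *full-transcriptome*
normalized values of those genes, and runs PCA (30 components).
Normalizing depth within the gene subset instead would cancel the very
program elevation being sought; this is why the projection consumes the
precomputed normalized layer. The cross-lineage aggregation score is the
fraction of mesodermal cells whose 15 nearest neighbors in the sub-PC
space are at least half epithelial; it is invariant to rigid rotations of
the space and quantifies what is otherwise read off a UMAP by eye.

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ overlap) with BH across sets.

## Spatial

Spot bundles follow 10x Visium conventions (MTX + `tissue_positions.csv`);
only in-tissue spots are kept, and barcode mismatches between matrix and
positions are errors. Spot clustering reuses the standard stack with 30
PCs and Louvain resolution 1.0 (the spot-cluster default; coordinates are
dimensionless pixels and no image handling is attempted). Log depth
normalization stands in for variance-stabilizing regression; the contract
is domain recovery, not numerical reproduction of any particular
normalization.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data at
the panel's native scale: five datasets of 800 cells × 1200 genes for the
atlas run, 400-cell two-dataset inputs for the null calibration (20
permutation replicates), 240 × 90 matrices over 10 seeds for consensus-NMF
k selection (k ∈ 2..5, 20 restarts), 600-cell datasets over 5 seeds for
the aggregation contrast, and a 20 × 20 spot grid. All stochastic steps
take explicit seeds; identical configuration and seed reproduce outputs
byte-for-byte.

## Known limitations

- The homeolog collapse interprets "higher expression" at the gene level
  (total count over the dataset); a per-cell maximum would create chimeric
  rows mixing L and S measurements. Totals tied are broken toward the
  lexicographically smaller source id.
- The MNN reference is a deliberately simple anchor method behind a
  pluggable contract; it does not reproduce CCA-anchor weighting and is
  validated by recovery of planted structure, not by equivalence to any
  external tool.
- Cycle-correlated-PC thresholds are dataset-specific by nature; the
  loading-sum baseline grows as the used gene set shrinks, so a threshold
  tuned for a 2000-gene HVG space does not transfer to a 500-gene one.
- Real cross-species atlases face ortholog divergence, platform and
  chemistry differences, and annotation noise that the generator does not
  emulate; results on it bound what the algorithms can do under ideal
  orthology, not what any particular dataset will yield.
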