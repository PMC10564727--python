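# limbatlas

Toolkit for cross-species single-cell analysis of limb development and
regeneration. It addresses a concrete comparative question: do axolotl limb
buds contain cells running the apical-ectodermal-ridge (AER) transcriptional
program found in other tetrapods, is that program fully re-deployed by the
wound epithelium (apical epithelial cap, AEC) during regeneration, and do
mesodermal connective-tissue (CT) cells display part of the epithelial AER
machinery? The package is written for computational biologists who want each
stage of such an analysis as a tested, reusable function rather than a
one-off notebook.

## What it implements

- **Shared gene spaces across species** (`genespace`): allopolyploid L/S
  homeologs and duplicate transcripts mapped to the same symbol are
  collapsed by keeping the source gene with the highest total count; the
  datasets are then restricted to one-to-one symbols present in every
  species.
- **Per-dataset preprocessing** (`preprocess`): QC filtering, depth
  normalization (10,000 counts/cell, log1p), standardized-variance HVG
  selection, exact PCA, Louvain clustering on a kNN graph, UMAP, and
  cluster downsampling. Cell-cycle handling follows the loading-sum rule:
  for each principal component the absolute loadings of the cycle genes are
  summed, components exceeding a threshold are flagged, the top 10% of
  genes per flagged component are removed, and PCA is re-run.
- **Integration** (`integrate`): cross-dataset feature ranking (genes
  ordered by the number of datasets calling them variable) and a
  mutual-nearest-neighbor anchor correction in joint PC space, plus the
  confusion-matrix integration-accuracy diagnostic and per-cluster species
  composition tables.
- **Cluster replicability** (`similarity`): MetaNeighbor-style
  neighbor-voting AUROC on a Spearman cell-cell network, with three feature
  inputs (binned-variance genes, cross-dataset HVGs, joint PCs). For a
  cluster pair (A, B) in two datasets the score is the probability that B's
  cells receive higher mean connectivity-to-A votes than the rest of their
  dataset; 0.5 means no evidence either way.
- **Per-cell gene-set activity** (`genesets`): AUCell-style ranking AUC
  (recovery of set members among each cell's top-ranked raw counts,
  normalized by the attainable maximum), cluster summaries with
  per-dataset/per-gene max normalization, and the marker co-expression
  statistic (fraction of cells expressing at least *m* of a marker panel).
- **Expression programs** (`programs`): Wilcoxon rank-sum differential
  expression with BH correction, marker intersection across comparisons,
  consensus NMF (restart pooling, outlier filtering, k-means consensus,
  NNLS usage refit, silhouette stability, and error/stability-based k
  selection), projection of selected clusters into gene-set sub-spaces, the
  cross-lineage aggregation score (fraction of mesodermal cells whose
  nearest neighbors are mostly epithelial), and hypergeometric
  over-representation.
- **Spatial spots** (`spatial`): Visium-style spot reading, clustering of
  tissue domains through the standard expression stack, and overlay-table
  export.
- **Synthetic ground truth** (`synthetic`): a negative-binomial
  multi-species generator that plants every feature the pipeline must
  detect — shared cell types, a species-private goblet analog, L/S homeolog
  row pairs, a cell-cycle confound, an AER program, a partially overlapping
  AEC program, program-carrying CT cells, and spatial sections with
  intact/blastema/AEC domains — so everything is testable without any
  download.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from limbatlas import synthetic, workflows, integrate

cfg = synthetic.SynthConfig(seed=7, negative_control_species=3)
panel = synthetic.generate_development_panel(cfg)
orthology = synthetic.make_orthology(cfg)

atlas = workflows.build_atlas(
    [adata for adata, _ in panel], orthology, cfg.cycle_symbols(), seed=0
)
truth = pd.concat([t for _, t in panel]).set_index("cell_id")
labels = atlas.labels.labels

print("shared genes:", atlas.n_shared_genes)
print("clusters:", labels.nunique())
print("ARI vs planted types:",
      round(adjusted_rand_score(truth.loc[labels.index, "true_type"], labels), 3))

comp = integrate.cluster_composition(
    labels, pd.Series(truth["species"], index=truth.index)
)
goblet = pd.crosstab(labels, truth.loc[labels.index, "true_type"])["goblet"].idxmax()
print("goblet-cluster top species fraction:", round(comp.loc[goblet].max(), 3))
```

Output:

```
shared genes: 1150
clusters: 6
ARI vs planted types: 1.0
goblet-cluster top species fraction: 1.0
```

The five 800-cell datasets collapse to a 1150-gene one-to-one space (50
species-private symbols drop out per dataset); after cycle-aware HVG
selection, MNN integration and Louvain clustering, the six planted cell
types are recovered exactly, and the goblet analog — present in only one
species — forms a single-species cluster rather than being forced onto
another type, the over-integration control.

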