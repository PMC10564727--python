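"""End-to-end convenience workflows wiring the pipeline stages together.

These are thin orchestration layers over the stage modules; every step can
also be run by hand. The atlas workflow mirrors the standard cross-species
recipe: collapse duplicate gene copies, intersect one-to-one symbols,
normalize and pick HVGs per dataset, remove cell-cycle-correlated PC genes,
rank integration features across datasets, anchor-correct in joint PC
space, and cluster the joint embedding.

The atlas-level graph is built with k = 30 neighbors and Louvain resolution
0.5 by default: the joint embedding pools many datasets, so a coarser
granularity than the per-dataset default recovers cell types rather than
within-type subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import genespace, integrate, preprocess

__all__ = ["AtlasResult", "build_atlas"]


@dataclass
class AtlasResult:
    matrices: list[ad.AnnData]  # shared-space, normalized datasets
    hvg_lists: dict[str, list[str]]  # per dataset, cycle genes removed
    features: list[str]
    embedding: integrate.JointEmbedding
    labels: preprocess.ClusterLabels
    cycle_reports: dict[str, preprocess.CycleReport] = field(default_factory=dict)

    @property
    def n_shared_genes(self) -> int:
        return int(self.matrices[0].uns.get("n_shared_genes",
                                            self.matrices[0].n_vars))


def build_atlas(
    panel: list[ad.AnnData],
    orthology: pd.DataFrame | None = None,
    cycle_genes: list[str] | None = None,
    n_hvg: int = 2000,
    cycle_threshold: float = 3.0,
    n_features: int = 1000,
    n_components: int = 30,
    knn: int = 30,
    resolution: float = 0.5,
    seed: int = 0,
) -> AtlasResult:
    """Run the full multi-dataset atlas pipeline and cluster the result."""
    import warnings

    if orthology is not None:
        panel = [genespace.collapse_duplicates(m, orthology) for m in panel]
    shared = genespace.build_shared_space(panel)

    hvgs: dict[str, list[str]] = {}
    reports: dict[str, preprocess.CycleReport] = {}
    norm: list[ad.AnnData] = []
    for m in shared:
        ds = m.obs["dataset"].iloc[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m2, hvg = preprocess.normalize_select_hvg(m, n_hvg=n_hvg)
        if cycle_genes:
            model = preprocess.run_pca(m2, hvg, n_components=n_components)
            _, report = preprocess.correct_cycle_pcs(
                m2, model, cycle_genes, threshold=cycle_threshold
            )
            reports[ds] = report
            removed = set(report.removed_genes)
            hvg = [g for g in hvg if g not in removed]
        hvgs[ds] = hvg
        norm.append(m2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = integrate.select_integration_features(hvgs, n=n_features)
    features = [g for g in features if all(g in m.var_names for m in norm)]
    embedding = integrate.mnn_integrate(
        norm, features, n_components=n_components, seed=seed
    )

    model = preprocess.PCAModel(
        loadings=pd.DataFrame(
            np.eye(embedding.coords.shape[1]),
            index=[f"f{i}" for i in range(embedding.coords.shape[1])],
            columns=embedding.coords.columns,
        ),
        scores=embedding.coords,
        explained_variance=np.ones(embedding.coords.shape[1]),
        genes=[],
    )
    labels = preprocess.cluster_cells(
        model, n_pcs=embedding.coords.shape[1], k=knn,
        resolution=resolution, seed=seed,
    )
    return AtlasResult(
        matrices=norm,
        hvg_lists=hvgs,
        features=features,
        embedding=embedding,
        labels=labels,
        cycle_reports=reports,
    )
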