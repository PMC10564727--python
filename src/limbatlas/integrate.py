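"""Cross-dataset integration and its diagnostics.

The integration contract is pluggable; the reference implementation anchors
datasets with mutual nearest neighbors (MNN) in a joint PC space and
corrects each incoming cell by a Gaussian-kernel-weighted average of its
anchors' displacement vectors. Diagnostics: the confusion-matrix integration
accuracy (normalized per integrated cluster) and per-cluster species or
dataset composition tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "JointEmbedding",
    "ConfusionAccuracy",
    "select_integration_features",
    "mnn_integrate",
    "integration_accuracy",
    "cluster_composition",
    "grouped_fraction",
]


@dataclass
class JointEmbedding:
    """Corrected joint coordinates for all cells of all datasets."""

    coords: pd.DataFrame  # cells x components
    dataset_ids: pd.Series  # per-cell dataset id, aligned with coords
    provenance: dict = field(default_factory=dict)


@dataclass
class ConfusionAccuracy:
    counts: pd.DataFrame  # reference clusters x integrated clusters
    normalized: pd.DataFrame  # counts / per-integrated-cluster column max


def select_integration_features(
    hvg_lists: dict[str, list[str]], n: int = 3000
) -> list[str]:
    """Rank genes for integration across datasets.

    Primary key: number of datasets in which the gene is highly variable
    (descending); tie-breaks: mean within-dataset HVG rank (ascending), then
    lexicographic id. Only genes appearing in every dataset's gene universe
    qualify — here the HVG lists are already in the shared space, so the
    ranking runs over the union and the caller guarantees the shared space.
    """
    stats: dict[str, list[int]] = {}
    for ds, hvg in hvg_lists.items():
        for rank, g in enumerate(hvg):
            stats.setdefault(g, []).append(rank)
    rows = [
        (g, len(ranks), float(np.mean(ranks))) for g, ranks in stats.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[2], r[0]))
    selected = [g for g, _, _ in rows[:n]]
    if len(rows) < n:
        warnings.warn(
            f"only {len(rows)} qualifying genes for n={n}; returning all"
        )
    return selected


def _scale_block(norm: np.ndarray) -> np.ndarray:
    mu = norm.mean(axis=0)
    sd = norm.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return np.clip((norm - mu) / sd, -10, 10)


def mnn_integrate(
    matrices: list[ad.AnnData],
    features: list[str],
    k_anchor: int = 20,
    n_components: int = 30,
    seed: int = 0,
) -> JointEmbedding:
    """MNN-anchor integration in joint PC space.

    Per-dataset z-scaling on the shared features, joint PCA, then an
    iterative pairwise merge starting from the largest dataset: mutual
    nearest neighbors between the merged set and the incoming dataset act as
    anchors, and every incoming cell is shifted by the kernel-weighted mean
    of its anchors' displacements.
    """
    if not matrices:
        raise ValueError("no datasets to integrate")
    for m in matrices:
        if "normalized" not in m.layers:
            raise ValueError("normalize each dataset before integration")
        missing = [g for g in features if g not in m.var_names]
        if missing:
            raise ValueError(
                f"dataset {m.obs['dataset'].iloc[0]} lacks features "
                f"{missing[:5]}"
            )

    blocks, ids, cells = [], [], []
    for m in matrices:
        cols = [list(m.var_names).index(g) for g in features]
        blocks.append(_scale_block(np.asarray(m.layers["normalized"])[:, cols]))
        ids += [m.obs["dataset"].iloc[0]] * m.n_obs
        cells += list(m.obs_names)
    X = np.vstack(blocks)
    X = X - X.mean(axis=0)
    n_components = min(n_components, min(X.shape))
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    joint = X @ Vt[:n_components].T

    ids_arr = np.array(ids)
    ds_order = (
        pd.Series(ids_arr).value_counts().index.tolist()
    )  # descending size, deterministic
    merged_idx = np.flatnonzero(ids_arr == ds_order[0])
    corrected = joint.copy()
    for ds in ds_order[1:]:
        new_idx = np.flatnonzero(ids_arr == ds)
        ref, new = corrected[merged_idx], corrected[new_idx]
        k = min(k_anchor, len(ref), len(new))
        nn_ref = NearestNeighbors(n_neighbors=k).fit(ref)
        nn_new = NearestNeighbors(n_neighbors=k).fit(new)
        _, ref_of_new = nn_ref.kneighbors(new)  # for each new cell: k ref ids
        _, new_of_ref = nn_new.kneighbors(ref)
        pairs = []
        ref_sets = [set(row) for row in new_of_ref]
        for j in range(len(new)):
            for r in ref_of_new[j]:
                if j in ref_sets[r]:
                    pairs.append((j, int(r)))
        if not pairs:
            warnings.warn(
                f"no MNN pairs for dataset {ds}; appended uncorrected"
            )
            merged_idx = np.concatenate([merged_idx, new_idx])
            continue
        anchor_new = np.array([p[0] for p in pairs])
        anchor_ref = np.array([p[1] for p in pairs])
        displacement = ref[anchor_ref] - new[anchor_new]
        anchor_pos = new[anchor_new]
        from scipy.spatial.distance import cdist

        d2 = cdist(new, anchor_pos, metric="sqeuclidean")
        # per-cell bandwidth at the k-anchor neighborhood scale, so each
        # correction averages over ~k anchor displacements
        kk = min(k, d2.shape[1]) - 1
        sigma2 = np.maximum(np.partition(d2, kk, axis=1)[:, kk], 1e-12)
        w = np.exp(-d2 / (2 * sigma2[:, None]))
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / np.maximum(w_sum, 1e-300), 0.0)
        corrected[new_idx] = new + w @ displacement
        merged_idx = np.concatenate([merged_idx, new_idx])

    coords = pd.DataFrame(
        corrected,
        index=pd.Index(cells, name="cell"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return JointEmbedding(
        coords=coords,
        dataset_ids=pd.Series(ids_arr, index=coords.index, name="dataset"),
        provenance={
            "method": "mnn",
            "features": list(features),
            "k_anchor": k_anchor,
            "seed": seed,
        },
    )


def integration_accuracy(
    reference_labels: pd.Series, atlas_labels: pd.Series
) -> ConfusionAccuracy:
    """Confusion matrix of per-dataset reference labels vs atlas labels.

    Normalized per integrated (atlas) cluster: each column is divided by its
    maximum count, so the dominant reference cluster of each atlas cluster
    reads 1.
    """
    common = reference_labels.index.intersection(atlas_labels.index)
    if len(common) == 0:
        raise ValueError("reference and atlas labels share no cells")
    counts = pd.crosstab(
        reference_labels.loc[common], atlas_labels.loc[common]
    )
    col_max = counts.max(axis=0)
    normalized = counts / col_max.replace(0, 1)
    return ConfusionAccuracy(counts=counts, normalized=normalized)


def cluster_composition(
    atlas_labels: pd.Series, group_ids: pd.Series
) -> pd.DataFrame:
    """Per-cluster fraction of cells from each dataset/species; rows sum to 1."""
    common = atlas_labels.index.intersection(group_ids.index)
    counts = pd.crosstab(atlas_labels.loc[common], group_ids.loc[common])
    return counts.div(counts.sum(axis=1), axis=0)


def grouped_fraction(
    composition: pd.DataFrame, cluster, groups: list[str]
) -> float:
    """Summed fraction of a subset of species/datasets in one cluster."""
    cols = [g for g in groups if g in composition.columns]
    if not cols:
        return 0.0
    return float(composition.loc[cluster, cols].sum())
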