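"""Per-dataset preprocessing: QC, normalization, HVG selection, PCA,
cell-cycle scoring and cycle-correlated-PC correction, graph clustering,
2-D embedding, and cluster downsampling.

Normalization is depth scaling to 10,000 counts per cell followed by
log1p. Highly variable genes are chosen by standardized variance: raw
counts are z-scored per gene under a fitted mean-variance trend, clipped,
and the variance of the clipped z-scores ranks the genes. Cell-cycle
correction follows the loading-sum rule: per principal component, the
absolute loadings of the cycle genes are summed; components whose sum
exceeds a threshold are cycle-correlated, their top 10% loading genes are
removed, and PCA is re-run.
"""

from __future__ import annotations

import math
import random as _random
import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCThresholds",
    "PCAModel",
    "CycleReport",
    "ClusterLabels",
    "qc_filter",
    "normalize_select_hvg",
    "run_pca",
    "score_cell_cycle",
    "correct_cycle_pcs",
    "cluster_cells",
    "embed_2d",
    "downsample_clusters",
]


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


@dataclass
class QCThresholds:
    """Cell-filtering thresholds on the three standard QC metrics."""

    max_mito_fraction: float = 1.0
    min_total_counts: int = 0
    max_total_counts: float = math.inf
    min_genes_detected: int = 0
    max_genes_detected: float = math.inf

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction outside [0, 1]")
        if self.min_total_counts > self.max_total_counts:
            raise ValueError("min_total_counts > max_total_counts")
        if self.min_genes_detected > self.max_genes_detected:
            raise ValueError("min_genes_detected > max_genes_detected")


@dataclass
class PCAModel:
    """Truncated PCA of the scaled expression matrix.

    loadings: genes x components, unit-norm columns, largest-magnitude entry
    of each column positive; scores: cells x components; components ordered
    by decreasing explained variance.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance: np.ndarray
    genes: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class CycleReport:
    loading_sums: pd.Series  # per-PC summed |loading| over cycle genes
    threshold: float
    flagged_pcs: list[int]
    removed_genes: list[str]
    s_score: pd.Series | None = None
    g2m_score: pd.Series | None = None


@dataclass
class ClusterLabels:
    labels: pd.Series  # cell id -> contiguous integer label from 0
    params: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return self.labels.to_numpy()


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds,
    mito_genes: list[str] | None = None,
) -> ad.AnnData:
    """Keep cells passing all three QC criteria; counts are never altered.

    The removed-per-criterion tally is stored in ``uns['qc_removed']``.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_genes = [g for g in (mito_genes or []) if g in adata.var_names]
    if mito_genes:
        mito = np.asarray(adata[:, mito_genes].X.sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    else:
        mito_frac = np.zeros(adata.n_obs)

    ok_mito = mito_frac <= thresholds.max_mito_fraction
    ok_tot = (totals >= thresholds.min_total_counts) & (
        totals <= thresholds.max_total_counts
    )
    ok_gen = (n_genes >= thresholds.min_genes_detected) & (
        n_genes <= thresholds.max_genes_detected
    )
    keep = ok_mito & ok_tot & ok_gen
    if not keep.any():
        raise ValueError("QC thresholds removed every cell")
    out = adata[keep].copy()
    out.uns["qc_removed"] = {
        "mito": int((~ok_mito).sum()),
        "total_counts": int((~ok_tot).sum()),
        "genes_detected": int((~ok_gen).sum()),
    }
    return out


def _standardized_variance(counts: np.ndarray) -> np.ndarray:
    """Variance of trend-clipped z-scores of raw counts, per gene."""
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    std_var = np.zeros(counts.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        return var
    lm, lv = np.log10(mean[ok]), np.log10(var[ok])
    coef = np.polyfit(lm, lv, deg=2)
    expected_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[ok])))
    z = (counts[:, ok] - mean[ok]) / expected_sd
    np.clip(z, -math.sqrt(n), math.sqrt(n), out=z)
    std_var[ok] = z.var(axis=0, ddof=1)
    return std_var


def normalize_select_hvg(
    adata: ad.AnnData, n_hvg: int = 2000, target_sum: float = 1e4
) -> tuple[ad.AnnData, list[str]]:
    """Depth-normalize, log1p, select HVGs, and z-score into a scaled layer.

    Adds layers ``normalized`` (log1p of counts scaled to ``target_sum`` per
    cell) and ``scaled`` (per-gene z-score of the normalized values, clipped
    at +/-10); stores the HVG list in ``uns['hvg']`` and returns it.
    """
    counts = _dense(adata.X).astype(float)
    totals = counts.sum(axis=1)
    totals[totals == 0] = 1.0
    normalized = np.log1p(counts / totals[:, None] * target_sum)

    if n_hvg > adata.n_vars:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds {adata.n_vars} genes; using all genes"
        )
        n_hvg = adata.n_vars
    std_var = _standardized_variance(counts)
    order = np.argsort(-std_var, kind="stable")
    hvg_idx = [i for i in order[:n_hvg] if std_var[i] > 0]
    hvg = [adata.var_names[i] for i in hvg_idx]

    mu = normalized.mean(axis=0)
    sd = normalized.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scaled = np.clip((normalized - mu) / sd, -10, 10)

    out = adata.copy()
    out.layers["normalized"] = normalized
    out.layers["scaled"] = scaled
    out.uns["hvg"] = list(hvg)
    out.var["standardized_variance"] = std_var
    return out, list(hvg)


def run_pca(
    adata: ad.AnnData, genes: list[str], n_components: int = 50
) -> PCAModel:
    """Exact truncated SVD of the scaled matrix restricted to ``genes``."""
    if "scaled" not in adata.layers:
        raise ValueError("scaled layer missing; run normalize_select_hvg first")
    cols = [list(adata.var_names).index(g) for g in genes]
    X = np.asarray(adata.layers["scaled"])[:, cols]
    X = X - X.mean(axis=0)
    max_rank = min(X.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; clamped"
        )
        n_components = max_rank
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:n_components].T
    # sign convention: largest-|entry| of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = X @ loadings
    expl = (s[:n_components] ** 2) / max(X.shape[0] - 1, 1)
    return PCAModel(
        loadings=pd.DataFrame(
            loadings, index=genes,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        scores=pd.DataFrame(
            scores, index=adata.obs_names,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        explained_variance=expl,
        genes=list(genes),
    )


def score_cell_cycle(
    adata: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    ctrl_per_gene: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M scores with expression-matched control genes.

    Score = mean normalized expression of the set genes minus the mean of a
    control pool sampled (seeded) from the same mean-expression bins. Phase
    is "S" if S > G2M and S > 0, "G2M" if G2M >= S and G2M > 0, else "G1".
    """
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer missing")
    norm = np.asarray(adata.layers["normalized"])
    genes = list(adata.var_names)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    gene_means = norm.mean(axis=0)
    ranks = pd.Series(gene_means, index=genes).rank(method="first")
    bins = pd.cut(ranks, bins=min(n_bins, len(genes)), labels=False)

    def set_score(members: list[str]) -> np.ndarray:
        present = [g for g in members if g in gene_pos]
        if not present:
            raise ValueError(f"no gene of the set is present: {members[:5]}...")
        member_set = set(present)
        ctrl: list[int] = []
        for g in present:
            pool = [gene_pos[x] for x in bins.index[bins == bins[g]]
                    if x not in member_set]
            if pool:
                take = min(ctrl_per_gene, len(pool))
                ctrl += list(rng.choice(pool, size=take, replace=False))
        set_mean = norm[:, [gene_pos[g] for g in present]].mean(axis=1)
        ctrl_mean = norm[:, sorted(set(ctrl))].mean(axis=1) if ctrl else 0.0
        return set_mean - ctrl_mean

    s_score = set_score(s_genes)
    g2m_score = set_score(g2m_genes)
    phase = np.where(
        (s_score > g2m_score) & (s_score > 0), "S",
        np.where((g2m_score >= s_score) & (g2m_score > 0), "G2M", "G1"),
    )
    return pd.DataFrame(
        {"S_score": s_score, "G2M_score": g2m_score, "phase": phase},
        index=adata.obs_names,
    )


def correct_cycle_pcs(
    adata: ad.AnnData,
    pca: PCAModel,
    cycle_genes: list[str],
    threshold: float,
    n_components: int | None = None,
) -> tuple[PCAModel, CycleReport]:
    """Remove cell-cycle-correlated components by re-running PCA.

    Per component, |loadings| of the cycle genes are summed; components with
    sum > threshold are flagged; for each flagged component the top 10% of
    genes by |loading| (ceil) are collected, the union is dropped from the
    gene list, and PCA is re-run. With no flagged component the model is
    returned unchanged.
    """
    present = [g for g in cycle_genes if g in pca.loadings.index]
    sums = pca.loadings.loc[present].abs().sum(axis=0) if present else pd.Series(
        0.0, index=pca.loadings.columns
    )
    flagged = [i for i, c in enumerate(pca.loadings.columns) if sums[c] > threshold]
    if not flagged:
        return pca, CycleReport(
            loading_sums=sums, threshold=threshold, flagged_pcs=[],
            removed_genes=[],
        )
    n_top = math.ceil(0.1 * len(pca.genes))
    removed: set[str] = set()
    for i in flagged:
        col = pca.loadings.iloc[:, i].abs()
        removed |= set(col.sort_values(ascending=False).index[:n_top])
    kept = [g for g in pca.genes if g not in removed]
    if not kept:
        raise ValueError("cycle correction removed every highly variable gene")
    new_model = run_pca(
        adata, kept,
        n_components=n_components or pca.n_components,
    )
    report = CycleReport(
        loading_sums=sums, threshold=threshold, flagged_pcs=flagged,
        removed_genes=sorted(removed),
    )
    return new_model, report


def _knn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = set()
    for i in range(coords.shape[0]):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=coords.shape[0], edges=sorted(edges))
    return g


def cluster_cells(
    pca: PCAModel,
    n_pcs: int = 15,
    k: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterLabels:
    """Louvain community detection on a Euclidean kNN graph of PC scores.

    Labels are contiguous integers from 0, ordered by decreasing cluster
    size; deterministic given the seed.
    """
    coords = pca.scores.iloc[:, :n_pcs].to_numpy()
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the {n} cells")
    g = _knn_graph(coords, k)
    rng = _random.Random(seed)
    igraph.set_random_number_generator(rng)
    try:
        part = g.community_multilevel(resolution=resolution)
    finally:
        igraph.set_random_number_generator(_random)
    raw = np.array(part.membership)
    order = pd.Series(raw).value_counts().index  # descending size
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[x] for x in raw], index=pca.scores.index, name="cluster"
    )
    return ClusterLabels(
        labels=labels,
        params={"n_pcs": n_pcs, "k": k, "resolution": resolution, "seed": seed},
    )


def embed_2d(pca: PCAModel, n_pcs: int = 15, seed: int = 0) -> pd.DataFrame:
    """UMAP 2-D embedding of the leading PC scores (reporting only)."""
    import umap

    if n_pcs > pca.n_components:
        warnings.warn(
            f"n_pcs={n_pcs} exceeds {pca.n_components} components; clamped"
        )
        n_pcs = pca.n_components
    coords = pca.scores.iloc[:, :n_pcs].to_numpy()
    emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(coords)
    return pd.DataFrame(emb, index=pca.scores.index, columns=["UMAP1", "UMAP2"])


def downsample_clusters(
    adata: ad.AnnData, labels: ClusterLabels, cap: int = 500, seed: int = 0
) -> ad.AnnData:
    """Halve clusters above the cap: n > cap -> ceil(n/2) cells, seeded."""
    lab = labels.labels.reindex(adata.obs_names)
    if lab.isna().any():
        raise ValueError("labels do not cover every cell")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for cl in sorted(lab.unique()):
        cells = lab.index[lab == cl].to_numpy()
        if len(cells) > cap:
            take = math.ceil(len(cells) / 2)
            cells = rng.choice(cells, size=take, replace=False)
        keep += list(cells)
    keep_set = set(keep)
    mask = [c in keep_set for c in adata.obs_names]
    return adata[mask].copy()
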