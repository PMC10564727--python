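"""Differential expression, marker intersection, consensus-NMF program
discovery, gene-set projection, cross-lineage aggregation, and
over-representation analysis.

The consensus NMF procedure repeats seeded NMF restarts, pools the
unit-normalized gene spectra, drops outlier spectra, clusters the remainder
into k groups, takes per-cluster medians as consensus spectra, and refits
cell usages by nonnegative least squares. k is chosen as the lowest-error
value among those whose spectra stability (mean silhouette) stays within
80% of the best.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .preprocess import PCAModel, run_pca

__all__ = [
    "wilcoxon_deg",
    "intersect_markers",
    "ConsensusModules",
    "consensus_nmf",
    "prepare_nmf_input",
    "call_specific_modules",
    "project_on_genesets",
    "cross_lineage_aggregation",
    "ora_hypergeometric",
]


def wilcoxon_deg(
    adata: ad.AnnData,
    cells_a: list[str],
    cells_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DEG table (group A vs group B).

    Per gene, on the normalized layer: mid-rank U statistic with normal
    approximation (tie and continuity corrected), BH adjustment across all
    tested genes, log2 fold change of group means with pseudocount 1, and
    the fraction of expressing cells per group.
    """
    overlap = set(cells_a) & set(cells_b)
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} cells")
    if not cells_a or not cells_b:
        raise ValueError("both groups must be non-empty")
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer missing")
    norm = pd.DataFrame(
        np.asarray(adata.layers["normalized"]),
        index=adata.obs_names, columns=adata.var_names,
    )
    xa = norm.loc[cells_a].to_numpy()
    xb = norm.loc[cells_b].to_numpy()
    res = scipy.stats.mannwhitneyu(
        xa, xb, axis=0, alternative="two-sided", method="asymptotic",
        use_continuity=True,
    )
    u, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    padj = multipletests(p, method="fdr_bh")[1]
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    lfc = np.log2((mean_a + 1) / (mean_b + 1))
    counts = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    pct_a = (counts.loc[cells_a].to_numpy() > 0).mean(axis=0)
    pct_b = (counts.loc[cells_b].to_numpy() > 0).mean(axis=0)
    table = pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "log2_fc": lfc,
            "U": u,
            "p": p,
            "p_adj": padj,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "significant": padj < alpha,
        }
    ).set_index("gene")
    return table.sort_values("p")


def intersect_markers(deg_tables: list[pd.DataFrame],
                      alpha: float = 0.05) -> list[str]:
    """Genes significantly up (lfc > 0, p_adj < alpha) in every comparison,
    sorted by their minimum fold change, descending."""
    if len(deg_tables) < 2:
        raise ValueError("need at least two DEG tables to intersect")
    up_sets = [
        set(t.index[(t["log2_fc"] > 0) & (t["p_adj"] < alpha)])
        for t in deg_tables
    ]
    shared = set.intersection(*up_sets)
    min_lfc = {
        g: min(t.loc[g, "log2_fc"] for t in deg_tables) for g in shared
    }
    return sorted(shared, key=lambda g: (-min_lfc[g], g))


@dataclass
class ConsensusModules:
    """Consensus factorization at one k."""

    k: int
    spectra: pd.DataFrame  # k x genes, rows unit L2 norm
    usages: pd.DataFrame  # cells x k, nonnegative
    error: float  # Frobenius reconstruction error
    stability: float  # mean silhouette of pooled spectra clustering
    n_restarts: int = 0
    seed: int = 0

    def top_genes(self, module: int, n: int = 20) -> list[str]:
        row = self.spectra.iloc[module]
        return list(row.sort_values(ascending=False).index[:n])


def prepare_nmf_input(adata: ad.AnnData,
                      genes: list[str] | None = None) -> pd.DataFrame:
    """Nonnegative NMF input: normalized values, HVG-restricted, per-gene
    z-scored and clipped at 0."""
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer missing")
    genes = genes or list(adata.uns.get("hvg", adata.var_names))
    cols = [list(adata.var_names).index(g) for g in genes]
    X = np.asarray(adata.layers["normalized"])[:, cols]
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, 0, None)
    return pd.DataFrame(Z, index=adata.obs_names, columns=genes)


def _unit_rows(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def _consensus_at_k(X: np.ndarray, k: int, n_restarts: int,
                    seed: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    pooled = []
    for r in range(n_restarts):
        model = NMF(
            n_components=k, init="random", solver="mu", max_iter=400,
            random_state=seed + 1000 * r, tol=1e-5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
        pooled.append(_unit_rows(model.components_))
    P = np.vstack(pooled)  # (n_restarts*k) x genes

    # drop outlier spectra: mean distance to 3 nearest pooled neighbors
    # above the 90th percentile
    D = cdist(P, P)
    np.fill_diagonal(D, np.inf)
    n_nn = min(3, len(P) - 1)
    if n_nn > 0:
        nn3 = np.sort(D, axis=1)[:, :n_nn].mean(axis=1)
        P = P[nn3 <= np.quantile(nn3, 0.9)]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(P)
    if len(set(assign)) > 1:
        stability = float(silhouette_score(P, assign))
    else:
        stability = 0.0
    spectra = np.vstack([
        np.median(P[assign == c], axis=0) for c in range(k)
    ])
    spectra = _unit_rows(spectra)

    # refit usages by NNLS per cell
    usages = np.vstack([
        scipy.optimize.nnls(spectra.T, row)[0] for row in X
    ])
    error = float(np.linalg.norm(X - usages @ spectra))
    return spectra, usages, error, stability


def consensus_nmf(
    X: pd.DataFrame,
    k_range: range | list[int] = range(5, 18),
    n_restarts: int = 20,
    seed: int = 0,
    stability_fraction: float = 0.8,
) -> tuple[dict[int, ConsensusModules], int]:
    """Consensus NMF over a range of k; returns per-k results and the
    selected k (lowest error among k with stability >= ``stability_fraction``
    times the best stability)."""
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    if (Xv < 0).any():
        raise ValueError("NMF input must be nonnegative")
    max_k = min(Xv.shape)
    ks = [k for k in k_range if k >= 1]
    clamped = [k for k in ks if k <= max_k]
    if len(clamped) < len(ks):
        warnings.warn(f"k values above {max_k} clamped away")
    results: dict[int, ConsensusModules] = {}
    genes = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"g{i}" for i in range(Xv.shape[1])
    ]
    cells = list(X.index) if isinstance(X, pd.DataFrame) else [
        f"c{i}" for i in range(Xv.shape[0])
    ]
    for k in clamped:
        spectra, usages, error, stability = _consensus_at_k(
            Xv, k, n_restarts, seed
        )
        results[k] = ConsensusModules(
            k=k,
            spectra=pd.DataFrame(
                spectra, index=[f"module_{i + 1}" for i in range(k)],
                columns=genes,
            ),
            usages=pd.DataFrame(
                usages, index=cells,
                columns=[f"module_{i + 1}" for i in range(k)],
            ),
            error=error,
            stability=stability,
            n_restarts=n_restarts,
            seed=seed,
        )
    best_stab = max(r.stability for r in results.values())
    eligible = [
        k for k, r in results.items()
        if r.stability >= stability_fraction * best_stab
    ]
    selected = min(eligible, key=lambda k: results[k].error)
    return results, selected


def call_specific_modules(
    usages: pd.DataFrame,
    labels: pd.Series,
    target_cluster,
    fold: float = 2.0,
) -> list[str]:
    """Modules whose mean usage in the target cluster is at least ``fold``
    times the maximum mean usage over every other cluster."""
    lab = labels.loc[usages.index]
    if target_cluster not in set(lab):
        raise ValueError(f"target cluster {target_cluster!r} absent")
    means = usages.groupby(lab).mean()
    target = means.loc[target_cluster]
    others = means.drop(index=target_cluster)
    if others.empty:
        return list(usages.columns)
    return [
        m for m in usages.columns
        if target[m] >= fold * others[m].max()
    ]


@dataclass
class GeneSetProjection:
    """Sub-space built from one gene set on selected clusters."""

    set_name: str
    genes_used: list[str]
    pcs: pd.DataFrame  # cells x n_pcs
    embedding: pd.DataFrame | None  # cells x 2, reporting only


def project_on_genesets(
    adata: ad.AnnData,
    gene_sets: list,
    labels: pd.Series,
    keep_clusters: list,
    top_n: int = 500,
    n_pcs: int = 30,
    seed: int = 0,
    compute_embedding: bool = False,
) -> dict[str, GeneSetProjection]:
    """Project the kept clusters into the space of each gene set.

    Cells are subset to ``keep_clusters``; each set contributes its top
    ``top_n`` genes present in the data (ranked by the set's weights when
    given, otherwise set order); the scaled sub-matrix is decomposed by PCA
    and optionally embedded in 2-D.
    """
    from .preprocess import embed_2d

    if "normalized" not in adata.layers:
        raise ValueError("normalized layer missing; depth-normalize first")
    lab = labels.loc[adata.obs_names]
    keep = lab.isin(keep_clusters)
    if not keep.any():
        raise ValueError(f"no cells in clusters {keep_clusters}")
    sub = adata[keep.to_numpy()].copy()
    norm = pd.DataFrame(
        np.asarray(sub.layers["normalized"]),
        index=sub.obs_names, columns=sub.var_names,
    )

    out: dict[str, GeneSetProjection] = {}
    for gs in gene_sets:
        members = list(gs.genes)
        if gs.weights is not None:
            w = gs.weights.reindex(members).fillna(-np.inf)
            members = list(w.sort_values(ascending=False).index)
        present = [g for g in members if g in sub.var_names][:top_n]
        if len(present) < 10:
            raise ValueError(
                f"gene set {gs.name!r}: only {len(present)} genes present "
                "(need >= 10)"
            )
        # scale the full-transcriptome-normalized values of the set genes
        block = sub[:, present].copy()
        X = norm[present].to_numpy()
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        block.layers["scaled"] = np.clip((X - mu) / sd, -10, 10)
        k = min(n_pcs, len(present), block.n_obs)
        model = run_pca(block, present, n_components=k)
        emb = embed_2d(model, n_pcs=k, seed=seed) if compute_embedding else None
        out[gs.name] = GeneSetProjection(
            set_name=gs.name,
            genes_used=present,
            pcs=model.scores,
            embedding=emb,
        )
    return out


def cross_lineage_aggregation(
    pcs: pd.DataFrame,
    lineage_labels: pd.Series,
    k: int = 15,
    epithelial: tuple[str, ...] = ("ectoderm", "epithelial"),
) -> tuple[float, pd.Series]:
    """Fraction of mesodermal cells embedded among epithelial cells.

    For each mesodermal cell, the fraction of its k nearest neighbors (in
    the sub-PC space) that are epithelial; the score is the fraction of
    mesodermal cells whose epithelial-neighbor fraction is at least 0.5.
    """
    lab = lineage_labels.loc[pcs.index]
    is_epi = lab.isin(epithelial).to_numpy()
    is_meso = ~is_epi
    if not is_epi.any() or not is_meso.any():
        raise ValueError("both lineages must be present")
    n = len(pcs)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than {n} cells")
    coords = pcs.to_numpy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh_epi = is_epi[idx[:, 1:]].mean(axis=1)
    frac = pd.Series(neigh_epi, index=pcs.index, name="epithelial_neighbor_frac")
    meso_frac = frac[is_meso]
    score = float((meso_frac >= 0.5).mean())
    return score, frac


def ora_hypergeometric(
    hits: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hits`` in each set.

    Sets are intersected with the universe (with a warning if trimmed);
    p-values are BH-adjusted across sets.
    """
    uni = set(universe)
    hit_set = set(hits) & uni
    if len(hit_set) < len(set(hits)):
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        inside = set(members) & uni
        if len(inside) < len(set(members)):
            warnings.warn(
                f"gene set {name!r}: {len(set(members)) - len(inside)} members "
                "outside the universe were dropped"
            )
        k = len(hit_set & inside)
        p = float(
            scipy.stats.hypergeom.sf(
                k - 1, len(uni), len(inside), len(hit_set)
            )
        )
        rows.append({"set": name, "overlap": k, "set_size": len(inside),
                     "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
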