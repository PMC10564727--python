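"""Cluster replicability across datasets by neighbor-voting AUROC.

Cells are connected by Spearman correlation over a chosen feature space;
each cell's correlation vector is rank-standardized to [0, 1]; a cluster in
one dataset "votes" for the cells of another dataset, and the AUROC measures
whether the cells of a candidate cluster outrank the rest of their dataset.
A score near 1 marks replicable cell types, 0.5 means the features carry no
signal for the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ClusterSimilarity", "select_similarity_features", "neighbor_voting_auroc"]

FEATURE_MODES = ("binned_variance", "hvg_top_n", "pc_top_n")


@dataclass
class ClusterSimilarity:
    """Symmetric (dataset, cluster)-pair AUROC table.

    Same-dataset off-diagonal pairs have no cross-dataset evidence and are
    NaN (missing, distinct from 0); the diagonal is 1 by convention.
    """

    scores: pd.DataFrame
    feature_mode: str

    def pair(self, a: tuple[str, str], b: tuple[str, str]) -> float:
        return float(self.scores.loc[[a], [b]].iloc[0, 0])


def _binned_variance_genes(norm: np.ndarray, genes: list[str],
                           n_bins: int = 10) -> set[str]:
    """Genes in the top variance quartile of their mean-expression bin."""
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    ranks = pd.Series(mean, index=genes).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(genes)), labels=False,
                   duplicates="drop")
    chosen: set[str] = set()
    for b in np.unique(bins):
        members = [g for g, bb in zip(genes, bins) if bb == b]
        take = math.ceil(len(members) / 4)
        mvar = pd.Series([var[genes.index(g)] for g in members], index=members)
        top = mvar[mvar > 0].sort_values(ascending=False).index[:take]
        chosen |= set(top)
    return chosen


def select_similarity_features(
    matrices: list[ad.AnnData],
    mode: str,
    n: int = 3000,
    hvg_lists: dict[str, list[str]] | None = None,
    joint_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the cells x features matrix for neighbor voting.

    Modes: ``binned_variance`` — genes in the top variance quartile of each
    of 10 mean-expression bins in every dataset; ``hvg_top_n`` — top-n genes
    of the cross-dataset HVG ranking; ``pc_top_n`` — first n joint PC scores
    (``joint_scores`` required).
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown mode {mode!r}; pick one of {FEATURE_MODES}")
    if mode == "pc_top_n":
        if joint_scores is None:
            raise ValueError("pc_top_n mode needs joint PC scores")
        return joint_scores.iloc[:, :n]

    for m in matrices:
        if "normalized" not in m.layers:
            raise ValueError("normalize datasets before feature selection")
    if mode == "binned_variance":
        selected: set[str] | None = None
        for m in matrices:
            genes = list(m.var_names)
            got = _binned_variance_genes(
                np.asarray(m.layers["normalized"]), genes
            )
            selected = got if selected is None else selected & got
        features = sorted(selected or set())
    else:  # hvg_top_n
        from .integrate import select_integration_features

        if hvg_lists is None:
            hvg_lists = {
                m.obs["dataset"].iloc[0]: list(m.uns["hvg"]) for m in matrices
            }
        ranked = select_integration_features(hvg_lists, n=n)
        features = [g for g in ranked
                    if all(g in m.var_names for m in matrices)][:n]
    if not features:
        raise ValueError("no features survived selection")
    blocks, cells = [], []
    for m in matrices:
        cols = [list(m.var_names).index(g) for g in features]
        blocks.append(np.asarray(m.layers["normalized"])[:, cols])
        cells += list(m.obs_names)
    return pd.DataFrame(np.vstack(blocks), index=pd.Index(cells, name="cell"),
                        columns=features)


def _auroc_from_votes(votes: np.ndarray, positives: np.ndarray) -> float:
    """Mid-rank Mann-Whitney AUROC: P(positive outranks negative), ties 0.5."""
    n_pos = int(positives.sum())
    n_neg = len(votes) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(votes)  # mid-ranks
    r_pos = ranks[positives].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def neighbor_voting_auroc(
    features: pd.DataFrame,
    dataset_ids: pd.Series,
    cluster_labels: pd.Series,
) -> ClusterSimilarity:
    """Pairwise cluster AUROC by neighbor voting on a Spearman network.

    For an ordered pair (A in ds1, B in ds2): each ds2 cell's vote is the
    mean of its rank-standardized correlations to the A cells; the AUROC
    asks whether B cells receive higher votes than the other ds2 cells. The
    reported score is the mean of the two directions.
    """
    cells = features.index
    ds = dataset_ids.loc[cells].to_numpy()
    cl = cluster_labels.loc[cells].to_numpy()
    n = len(cells)
    if len(set(ds)) < 2:
        raise ValueError("need at least two datasets")

    # Spearman network: Pearson of within-cell feature ranks; a cell with a
    # constant feature vector has undefined correlations, set to 0
    R = np.apply_along_axis(rankdata, 1, features.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(R)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, np.nan)
    # rank-standardize each cell's correlation vector to [0, 1], self excluded
    S = np.empty_like(C)
    for i in range(n):
        row = C[i]
        mask = ~np.isnan(row)
        S[i] = np.nan
        S[i, mask] = rankdata(row[mask]) / mask.sum()

    pairs = sorted(set(zip(ds, cl)), key=lambda p: (str(p[0]), str(p[1])))
    index = pd.MultiIndex.from_tuples(pairs, names=["dataset", "cluster"])
    scores = pd.DataFrame(np.nan, index=index, columns=index)

    members = {p: np.flatnonzero((ds == p[0]) & (cl == p[1])) for p in pairs}
    ds_cells = {d: np.flatnonzero(ds == d) for d in set(ds)}

    def directed(a: tuple, b: tuple) -> float:
        """Votes from cluster a's cells onto b's dataset; AUROC of b."""
        target = ds_cells[b[0]]
        votes = np.nanmean(S[np.ix_(target, members[a])], axis=1)
        positives = np.isin(target, members[b])
        return _auroc_from_votes(votes, positives)

    for a in pairs:
        for b in pairs:
            if a == b:
                scores.loc[[a], [b]] = 1.0
            elif a[0] == b[0]:
                continue  # same dataset: no cross-dataset evidence
            elif scores.loc[[a], [b]].isna().iloc[0, 0]:
                fwd, rev = directed(a, b), directed(b, a)
                # a dataset with a single cluster yields no negatives in its
                # direction; the pair's score is then missing, not 0
                val = (
                    math.nan
                    if math.isnan(fwd) or math.isnan(rev)
                    else float((fwd + rev) / 2)
                )
                scores.loc[[a], [b]] = val
                scores.loc[[b], [a]] = val
    return ClusterSimilarity(scores=scores, feature_mode="custom")
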