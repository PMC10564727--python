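"""Cross-species shared gene space construction.

Allopolyploid homeologs (L/S copies) and duplicate transcripts annotated to
the same symbol are collapsed to a single row by keeping the source gene
with the highest total raw count across the dataset; datasets are then
restricted to the one-to-one symbols present in every species.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["collapse_duplicates", "build_shared_space"]


def _totals(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return np.asarray(X.sum(axis=0)).ravel()
    return np.asarray(X).sum(axis=0)


def collapse_duplicates(adata: ad.AnnData, orthology: pd.DataFrame) -> ad.AnnData:
    """Collapse multi-mapped source genes to one row per shared symbol.

    For every shared symbol mapped by two or more source genes, only the
    source row with the greatest total count across all cells is kept (ties
    broken by lexicographically smaller source id); kept rows are relabelled
    by their shared symbol. The kept column's counts are untouched — no
    summing across copies, which would create chimeric expression profiles.
    """
    species = adata.obs["species"].iloc[0] if "species" in adata.obs else None
    orth = orthology
    if species is not None and "species" in orth.columns:
        sub = orth[orth["species"] == species]
        if len(sub):
            orth = sub
    mapping = orth.set_index("source_gene_id")["shared_symbol"]
    missing = [g for g in adata.var_names if g not in mapping.index]
    if missing:
        shown = ", ".join(missing[:10])
        raise KeyError(
            f"{len(missing)} gene ids absent from the orthology table "
            f"(first: {shown})"
        )
    symbols = mapping.loc[adata.var_names].to_numpy()
    totals = _totals(adata)

    order = pd.DataFrame(
        {
            "pos": np.arange(adata.n_vars),
            "source": np.asarray(adata.var_names),
            "symbol": symbols,
            "total": totals,
        }
    )
    # max total wins; ties -> lexicographically smaller source id
    order = order.sort_values(
        ["symbol", "total", "source"], ascending=[True, False, True], kind="stable"
    )
    keep = order.drop_duplicates("symbol", keep="first").sort_values("pos")
    out = adata[:, keep["pos"].to_numpy()].copy()
    out.var_names = pd.Index(keep["symbol"].to_numpy(), name="gene")
    return out


def build_shared_space(
    matrices: list[ad.AnnData], orthology: pd.DataFrame | None = None
) -> list[ad.AnnData]:
    """Restrict every (already collapsed) matrix to the common symbols.

    The intersection is ordered by the first matrix's gene order, giving
    identical gene id vectors across all outputs. The retained-gene count is
    recorded in each output's ``uns['n_shared_genes']``.
    """
    if not matrices:
        raise ValueError("no matrices given")
    common = set(matrices[0].var_names)
    for m in matrices[1:]:
        common &= set(m.var_names)
    if not common:
        raise ValueError("empty shared-symbol intersection across datasets")
    order = [g for g in matrices[0].var_names if g in common]
    out = []
    for m in matrices:
        sub = m[:, order].copy()
        sub.uns["n_shared_genes"] = len(order)
        out.append(sub)
    return out
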