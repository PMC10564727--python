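"""Visium-style spot analysis: reading spot bundles, clustering spots with
the standard expression stack, and exporting gene/score overlay tables."""

from __future__ import annotations

import os
import warnings

import anndata as ad
import numpy as np
import pandas as pd

from . import io as _io
from .preprocess import ClusterLabels, cluster_cells, normalize_select_hvg, run_pca

__all__ = ["read_spots", "cluster_spots", "overlay_table"]


def read_spots(
    matrix_path: str | os.PathLike, positions_path: str | os.PathLike
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Read a spot MTX bundle plus tissue positions; keep in-tissue spots."""
    adata = _io.read_10x_mtx(matrix_path)
    positions = _io.read_positions(positions_path)
    pos_bc = set(positions["barcode"])
    mat_bc = set(adata.obs_names)
    missing = sorted(mat_bc ^ pos_bc)
    if missing:
        raise ValueError(
            f"{len(missing)} barcodes differ between matrix and positions "
            f"(e.g. {missing[:5]})"
        )
    in_tissue = positions.loc[positions["in_tissue"] == 1, "barcode"]
    if in_tissue.empty:
        raise ValueError("no spot is inside the tissue")
    keep = [bc for bc in adata.obs_names if bc in set(in_tissue)]
    adata = adata[keep].copy()
    positions = positions[positions["barcode"].isin(keep)].reset_index(drop=True)
    return adata, positions


def cluster_spots(
    adata: ad.AnnData,
    n_pcs: int = 30,
    resolution: float = 1.0,
    k: int = 20,
    seed: int = 0,
    n_hvg: int = 2000,
) -> ClusterLabels:
    """Cluster spots with the standard stack: normalize, HVG, PCA, Louvain."""
    if adata.n_obs < 2:
        raise ValueError("need at least two spots")
    adata, hvg = normalize_select_hvg(adata, n_hvg=min(n_hvg, adata.n_vars))
    model = run_pca(adata, hvg, n_components=min(n_pcs, len(hvg),
                                                 adata.n_obs - 1))
    return cluster_cells(model, n_pcs=model.n_components, k=min(k, adata.n_obs - 1),
                         resolution=resolution, seed=seed)


def overlay_table(
    adata: ad.AnnData,
    positions: pd.DataFrame,
    genes: list[str] | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long table (spot, x, y, item, value) for plotting expression overlays.

    Gene values are depth-normalized log1p expression scaled to the maximum
    over spots; score columns are exported as given, scaled likewise. Absent
    genes are skipped with a warning.
    """
    pos = positions.set_index("barcode").loc[list(adata.obs_names)]
    x = pos["pxl_col_in_fullres"].to_numpy()
    y = pos["pxl_row_in_fullres"].to_numpy()

    columns: dict[str, np.ndarray] = {}
    if genes:
        counts = np.asarray(adata.X, dtype=float)
        totals = counts.sum(axis=1)
        totals[totals == 0] = 1.0
        norm = np.log1p(counts / totals[:, None] * 1e4)
        for g in genes:
            if g not in adata.var_names:
                warnings.warn(f"gene {g!r} absent; skipped")
                continue
            columns[g] = norm[:, list(adata.var_names).index(g)]
    if scores is not None:
        aligned = scores.reindex(adata.obs_names)
        for c in scores.columns:
            columns[c] = aligned[c].to_numpy()

    rows = []
    for item, vals in columns.items():
        vmax = np.nanmax(vals) if len(vals) else 0.0
        scalef = vmax if vmax > 0 else 1.0
        for bc, xi, yi, v in zip(adata.obs_names, x, y, vals):
            rows.append({"spot": bc, "x": xi, "y": yi, "item": item,
                         "value": v / scalef})
    return pd.DataFrame(rows)
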