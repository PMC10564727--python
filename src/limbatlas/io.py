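"""Reading and writing the on-disk formats used across the pipeline.

Count matrices travel as 10x-style MTX bundles (``matrix.mtx`` with genes as
MTX rows and cells as MTX columns, plus ``features.tsv`` and
``barcodes.tsv``); in memory they are :class:`anndata.AnnData` objects with
cells as observations. Gene sets use GMT, orthology tables and truth tables
plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_gmt",
    "write_gmt",
    "read_orthology",
    "write_orthology",
    "read_positions",
    "write_positions",
]

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def write_10x_mtx(adata: ad.AnnData, path: str | os.PathLike) -> None:
    """Write counts as a 10x-style bundle (MTX is genes x cells)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(path / "matrix.mtx"), X.T.tocoo().astype(np.int64))
    pd.Series(adata.var_names).to_csv(
        path / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_10x_mtx(path: str | os.PathLike) -> ad.AnnData:
    """Read a bundle written by :func:`write_10x_mtx`; transposes to cells x genes."""
    path = Path(path)
    X = scipy.io.mmread(str(path / "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_orthology(path: str | os.PathLike) -> pd.DataFrame:
    """Read an orthology table TSV with columns
    source_gene_id, species, shared_symbol, group_tag."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_gene_id", "species", "shared_symbol", "group_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orthology table missing columns: {sorted(missing)}")
    return df


def write_orthology(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_positions(path: str | os.PathLike) -> pd.DataFrame:
    """Read a Visium-style tissue position table (CSV with header)."""
    df = pd.read_csv(path)
    missing = set(POSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"positions table missing columns: {sorted(missing)}")
    return df


def write_positions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)
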