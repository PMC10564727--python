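import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from limbatlas import preprocess, synthetic

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_config():
    """Compact two-species panel used by unit tests (fast to generate)."""
    return synthetic.SynthConfig(
        n_species=2,
        cells_per_dataset=300,
        n_genes=600,
        shared_types=("AER", "ectoderm", "mesoderm"),
        private_types={0: "goblet"},
        n_private_genes=30,
        n_homeolog_genes=40,
        homeolog_species=1,
        marker_genes_per_type=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synthetic.generate_development_panel(small_config)


@pytest.fixture(scope="session")
def small_orthology(small_config):
    return synthetic.make_orthology(small_config)


@pytest.fixture(scope="session")
def normalized_dataset(small_panel):
    """First dataset of the small panel with normalized/scaled layers."""
    adata, truth = small_panel[0]
    out, hvg = preprocess.normalize_select_hvg(adata, n_hvg=400)
    return out, hvg, truth.set_index("cell_id")


def toy_counts(matrix, genes=None, cells=None, **obs):
    """AnnData from a plain list-of-lists count matrix (cells x genes)."""
    X = np.asarray(matrix, dtype=float)
    n, g = X.shape
    genes = genes or [f"g{j}" for j in range(g)]
    cells = cells or [f"c{i}" for i in range(n)]
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    for key, val in obs.items():
        adata.obs[key] = val
    return adata
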