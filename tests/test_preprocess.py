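"""QC, normalization, PCA (with brute-force oracle), cycle correction,
clustering, embedding, and downsampling."""

import math

import numpy as np
import pandas as pd
import pytest

from limbatlas import preprocess
from limbatlas.preprocess import QCThresholds
from tests.conftest import toy_counts


# --- qc_filter --------------------------------------------------------------


def test_qc_identity_at_open_thresholds():
    adata = toy_counts([[1, 0], [0, 2], [3, 3]])
    out = preprocess.qc_filter(adata, QCThresholds())
    assert out.n_obs == 3
    assert np.array_equal(np.asarray(out.X), np.asarray(adata.X))


def test_qc_mito_fraction_toy():
    # mito fractions [0.02, 0.3, 0.05] against max 0.1: cells 1 and 3 kept
    adata = toy_counts(
        [[98, 2], [70, 30], [95, 5]], genes=["g", "mt-1"]
    )
    out = preprocess.qc_filter(
        adata, QCThresholds(max_mito_fraction=0.1), mito_genes=["mt-1"]
    )
    assert list(out.obs_names) == ["c0", "c2"]
    assert out.uns["qc_removed"]["mito"] == 1


def test_qc_zero_count_cell_removed_and_all_removed_errors():
    adata = toy_counts([[0, 0], [1, 1]])
    out = preprocess.qc_filter(adata, QCThresholds(min_total_counts=1))
    assert list(out.obs_names) == ["c1"]
    with pytest.raises(ValueError):
        preprocess.qc_filter(adata, QCThresholds(min_total_counts=10))


def test_qc_retained_set_is_intersection_of_criteria():
    adata = toy_counts(
        [[10, 0, 0], [5, 5, 30], [1, 0, 0], [20, 20, 2]],
        genes=["a", "b", "mt-1"],
    )
    t = QCThresholds(max_mito_fraction=0.2, min_total_counts=5,
                     min_genes_detected=2)
    out = preprocess.qc_filter(adata, t, mito_genes=["mt-1"])
    assert list(out.obs_names) == ["c3"]


# --- normalize_select_hvg ---------------------------------------------------


def test_normalization_formula():
    adata = toy_counts([[10, 90], [20, 180]])
    out, _ = preprocess.normalize_select_hvg(adata, n_hvg=2)
    norm = out.layers["normalized"]
    # cell totals 100 and 200; gene 0 counts 10 and 20
    assert norm[0, 0] == pytest.approx(math.log1p(10 / 100 * 1e4))
    assert norm[1, 0] == pytest.approx(math.log1p(20 / 200 * 1e4))


def test_constant_gene_never_hvg():
    rng = np.random.default_rng(0)
    X = rng.poisson(5.0, size=(50, 10)).astype(float)
    X[:, 3] = 7.0  # constant gene
    adata = toy_counts(X)
    _, hvg = preprocess.normalize_select_hvg(adata, n_hvg=5)
    assert "g3" not in hvg


def test_hvg_captures_planted_program(small_config, small_panel):
    """Planted program genes have high between-type variance and should
    dominate the top of the HVG ranking."""
    adata, _ = small_panel[0]
    _, hvg = preprocess.normalize_select_hvg(adata, n_hvg=300)
    prog = set(small_config.program_symbols())
    recall = len(prog & set(hvg)) / len(prog)
    assert recall >= 0.8


def test_scaled_layer_clipped_and_centered(normalized_dataset):
    adata, hvg, _ = normalized_dataset
    scaled = adata.layers["scaled"]
    assert np.abs(scaled).max() <= 10 + 1e-9
    assert np.allclose(scaled.mean(axis=0), 0.0, atol=0.05)


# --- run_pca ----------------------------------------------------------------


def test_pca_matches_brute_force_eigendecomposition():
    X = np.array([[2.0, 0.0, 1.0],
                  [0.0, 1.0, 3.0],
                  [1.0, 1.0, 0.0],
                  [3.0, 2.0, 2.0]])
    adata = toy_counts(X)
    adata.layers["scaled"] = X.copy()
    model = preprocess.run_pca(adata, list(adata.var_names), n_components=3)
    # oracle: eigenvalues of the covariance of the centered matrix
    Xc = X - X.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
    assert np.allclose(model.explained_variance, eig, atol=1e-10)
    # scores = centered matrix times loadings
    assert np.allclose(
        model.scores.to_numpy(), Xc @ model.loadings.to_numpy(), atol=1e-8
    )


def test_pca_rank1_and_reconstruction():
    u = np.arange(1, 7, dtype=float)[:, None]
    v = np.array([[1.0, 2.0, 0.5]])
    X = u @ v
    adata = toy_counts(X)
    adata.layers["scaled"] = X.copy()
    model = preprocess.run_pca(adata, list(adata.var_names), n_components=3)
    assert model.explained_variance[1:].max() < 1e-8
    Xc = X - X.mean(axis=0)
    recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
    assert np.allclose(recon, Xc, atol=1e-6)


def test_pca_loading_columns_unit_norm_and_sign(normalized_dataset):
    adata, hvg, _ = normalized_dataset
    model = preprocess.run_pca(adata, hvg, n_components=10)
    L = model.loadings.to_numpy()
    assert np.allclose(np.linalg.norm(L, axis=0), 1.0, atol=1e-6)
    for j in range(L.shape[1]):
        assert L[np.abs(L[:, j]).argmax(), j] > 0
    # components ordered by decreasing explained variance
    assert np.all(np.diff(model.explained_variance) <= 1e-12)


def test_pca_clamps_excess_components():
    X = np.random.default_rng(0).normal(size=(5, 3))
    adata = toy_counts(X)
    adata.layers["scaled"] = X.copy()
    with pytest.warns(UserWarning, match="clamped"):
        model = preprocess.run_pca(adata, list(adata.var_names),
                                   n_components=10)
    assert model.n_components == 3


# --- score_cell_cycle -------------------------------------------------------


def test_cell_cycle_scores_toy():
    rng = np.random.default_rng(1)
    X = rng.poisson(5.0, size=(30, 20)).astype(float)
    s_genes = ["g0", "g1", "g2"]
    X[:10, :3] *= 8  # first 10 cells over-express S genes only
    adata = toy_counts(X)
    adata, _ = preprocess.normalize_select_hvg(adata, n_hvg=20)
    scores = preprocess.score_cell_cycle(
        adata, s_genes, ["g5", "g6", "g7"], seed=0
    )
    assert (scores.iloc[:10]["S_score"] > 0).all()
    assert (scores.iloc[:10]["phase"] == "S").all()
    # scores invariant under duplicating the population
    dup = adata.concatenate(adata, index_unique="-")
    dup.layers["normalized"] = np.vstack([adata.layers["normalized"]] * 2)
    s2 = preprocess.score_cell_cycle(dup, s_genes, ["g5", "g6", "g7"], seed=0)
    assert np.allclose(
        s2["S_score"].to_numpy()[:30], scores["S_score"].to_numpy()
    )


def test_cell_cycle_no_set_gene_errors(normalized_dataset):
    adata, _, _ = normalized_dataset
    with pytest.raises(ValueError):
        preprocess.score_cell_cycle(adata, ["absent1"], ["absent2"])


# --- correct_cycle_pcs ------------------------------------------------------


def test_cycle_correction_noop_cases(normalized_dataset):
    adata, hvg, _ = normalized_dataset
    model = preprocess.run_pca(adata, hvg, n_components=10)
    same, report = preprocess.correct_cycle_pcs(
        adata, model, ["CYC000"], threshold=math.inf
    )
    assert report.flagged_pcs == [] and same is model
    # no cycle gene among genes used -> all sums zero
    _, rep2 = preprocess.correct_cycle_pcs(
        adata, model, ["not_a_gene"], threshold=0.5
    )
    assert rep2.loading_sums.max() == 0 and rep2.flagged_pcs == []


def test_cycle_correction_flags_and_decorrelates(small_config, small_panel):
    adata, truth = small_panel[0]
    adata, hvg = preprocess.normalize_select_hvg(adata, n_hvg=600)
    model = preprocess.run_pca(adata, hvg, n_components=20)
    cyc = small_config.cycle_symbols()
    fixed, report = preprocess.correct_cycle_pcs(adata, model, cyc,
                                                 threshold=1.0)
    assert len(report.flagged_pcs) >= 1
    # removed count equals the union of per-PC top-10% sets
    n_top = math.ceil(0.1 * len(model.genes))
    union = set()
    for i in report.flagged_pcs:
        col = model.loadings.iloc[:, i].abs()
        union |= set(col.sort_values(ascending=False).index[:n_top])
    assert set(report.removed_genes) == union
    cycling = truth["cycling"].astype(float).to_numpy()
    corr = [abs(np.corrcoef(fixed.scores.iloc[:, j], cycling)[0, 1])
            for j in range(fixed.n_components)]
    assert max(corr) < 0.3


# --- cluster_cells ----------------------------------------------------------


def _blob_model(rng, n=100, sep=10.0):
    a = rng.normal(0, 1, size=(n, 5))
    b = rng.normal(0, 1, size=(n, 5)) + sep
    X = np.vstack([a, b])
    scores = pd.DataFrame(X, index=[f"c{i}" for i in range(2 * n)],
                          columns=[f"PC{i+1}" for i in range(5)])
    return preprocess.PCAModel(
        loadings=pd.DataFrame(np.eye(5)), scores=scores,
        explained_variance=np.ones(5), genes=[],
    )


def test_louvain_separates_two_blobs():
    model = _blob_model(np.random.default_rng(0))
    labels = preprocess.cluster_cells(model, n_pcs=5, k=15, seed=0)
    from sklearn.metrics import adjusted_rand_score

    truth = [0] * 100 + [1] * 100
    assert adjusted_rand_score(truth, labels.as_array()) == 1.0
    assert sorted(set(labels.as_array())) == [0, 1]


def test_louvain_low_resolution_single_cluster():
    model = _blob_model(np.random.default_rng(0), sep=1.0)
    labels = preprocess.cluster_cells(model, n_pcs=5, k=30,
                                      resolution=0.001, seed=0)
    assert labels.labels.nunique() == 1


def test_louvain_deterministic_and_k_validation():
    model = _blob_model(np.random.default_rng(1))
    l1 = preprocess.cluster_cells(model, n_pcs=5, k=10, seed=4)
    l2 = preprocess.cluster_cells(model, n_pcs=5, k=10, seed=4)
    assert l1.labels.equals(l2.labels)
    with pytest.raises(ValueError):
        preprocess.cluster_cells(model, n_pcs=5, k=200, seed=0)


# --- embed_2d ---------------------------------------------------------------


def test_embedding_shape_determinism_and_blob_separation():
    model = _blob_model(np.random.default_rng(2), n=60)
    e1 = preprocess.embed_2d(model, n_pcs=5, seed=0)
    e2 = preprocess.embed_2d(model, n_pcs=5, seed=0)
    assert e1.shape == (120, 2)
    assert np.allclose(e1.to_numpy(), e2.to_numpy())
    a, b = e1.to_numpy()[:60], e1.to_numpy()[60:]
    intra = np.linalg.norm(a - a.mean(0), axis=1).mean()
    inter = np.linalg.norm(a.mean(0) - b.mean(0))
    assert inter > intra


# --- downsample_clusters ----------------------------------------------------


@pytest.mark.parametrize("size,expected", [(1200, 600), (400, 400), (501, 251)])
def test_downsample_halves_above_cap(size, expected):
    X = np.ones((size, 2))
    adata = toy_counts(X)
    labels = preprocess.ClusterLabels(
        labels=pd.Series(0, index=adata.obs_names)
    )
    out = preprocess.downsample_clusters(adata, labels, cap=500, seed=0)
    assert out.n_obs == expected
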