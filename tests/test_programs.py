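"""DEG statistics with exact-enumeration oracle, marker intersection,
consensus NMF, module specificity, projection, aggregation, and ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from limbatlas import programs, synthetic
from limbatlas.genesets import GeneSet
from tests.conftest import toy_counts


def _deg_input(values_a, values_b):
    """AnnData with one gene whose normalized values are given per group."""
    X = np.array(values_a + values_b, dtype=float)[:, None]
    adata = toy_counts(X, genes=["g"])
    adata.layers["normalized"] = X.copy()
    cells_a = [f"c{i}" for i in range(len(values_a))]
    cells_b = [f"c{i}" for i in range(len(values_a), len(values_a) + len(values_b))]
    return adata, cells_a, cells_b


def exact_ranksum_p(a, b):
    """Two-sided rank-sum p by enumerating all group assignments
    (2 x min tail, clipped at 1 — the standard exact convention)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = rankdata(pooled)
    obs = ranks[:n_a].sum()
    stats = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), n_a)
    ]
    m = len(stats)
    lower = sum(s <= obs + 1e-12 for s in stats) / m
    upper = sum(s >= obs - 1e-12 for s in stats) / m
    return min(1.0, 2 * min(lower, upper))


def test_ranksum_matches_exact_enumeration_small_groups():
    """Asymptotic p within 0.06 of exact enumeration for all small toys."""
    # exhaustive over distinct-valued toys with >= 3 cells per group and
    # <= 8 cells total (tied degenerate cases are checked separately; the
    # approximation is not meant for groups of 2)
    cases = [([1, 2, 3], [4, 5, 6])]
    for n1, n2 in [(3, 3), (3, 4), (4, 4), (3, 5)]:
        vals = np.arange(n1 + n2, dtype=float) + 1
        for combo in itertools.combinations(range(n1 + n2), n1):
            a = [vals[i] for i in combo]
            b = [vals[i] for i in range(n1 + n2) if i not in combo]
            cases.append((a, b))
    for a, b in cases:
        adata, ca, cb = _deg_input(a, b)
        table = programs.wilcoxon_deg(adata, ca, cb)
        exact = exact_ranksum_p(a, b)
        assert abs(table["p"].iloc[0] - exact) <= 0.06
    # the printed example: exact two-sided p of separated triples is 0.1
    assert exact_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_identical_groups_p_one():
    adata, ca, cb = _deg_input([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
    table = programs.wilcoxon_deg(adata, ca, cb)
    assert table["p"].iloc[0] == pytest.approx(1.0)
    assert table["log2_fc"].iloc[0] == pytest.approx(0.0)


def test_deg_group_validation():
    adata, ca, cb = _deg_input([1.0], [2.0])
    with pytest.raises(ValueError, match="overlap"):
        programs.wilcoxon_deg(adata, ca, ca)
    with pytest.raises(ValueError):
        programs.wilcoxon_deg(adata, [], cb)


def hand_bh(ps):
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = math.inf
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, ps[i] * m / (rank_pos + 1))
        adj[i] = min(running, 1.0)
    return adj


def test_bh_matches_hand_formula_on_all_permutations():
    from statsmodels.stats.multitest import multipletests

    base = [0.01, 0.02, 0.03, 0.2, 0.9]
    for perm in itertools.permutations(base):
        got = multipletests(list(perm), method="fdr_bh")[1]
        assert np.allclose(got, hand_bh(list(perm)), atol=1e-12)
    # printed example
    assert np.allclose(
        multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1],
        [0.03, 0.03, 0.03],
    )


def test_intersect_markers_logic():
    t1 = pd.DataFrame(
        {"log2_fc": [1.0, 2.0, -1.0], "p_adj": [0.01, 0.04, 0.001]},
        index=["A", "B", "C"],
    )
    t2 = pd.DataFrame(
        {"log2_fc": [0.5, 3.0, 1.0], "p_adj": [0.01, 0.01, 0.2]},
        index=["A", "B", "C"],
    )
    got = programs.intersect_markers([t1, t2])
    # B (min lfc 2.0) before A (min lfc 0.5); C fails in both directions
    assert got == ["B", "A"]
    with pytest.raises(ValueError):
        programs.intersect_markers([t1])


def test_marker_intersection_recovers_planted_aer_markers(small_config,
                                                          small_panel):
    """AER-vs-all and AER-vs-ectoderm DEG intersection recovers >= 80% of
    the planted program genes."""
    from limbatlas import preprocess

    adata, truth = small_panel[0]
    adata, _ = preprocess.normalize_select_hvg(adata, n_hvg=400)
    t = truth.set_index("cell_id")
    aer = list(t.index[t["true_type"] == "AER"])
    non_aer = list(t.index[t["true_type"] != "AER"])
    ecto = list(t.index[t["true_type"] == "ectoderm"])
    t_all = programs.wilcoxon_deg(adata, aer, non_aer)
    t_ecto = programs.wilcoxon_deg(adata, aer, ecto)
    markers = programs.intersect_markers([t_all, t_ecto])
    prog = set(small_config.program_symbols())
    recall = len(prog & set(markers)) / len(prog)
    assert recall >= 0.8


# --- consensus NMF ----------------------------------------------------------


def test_nmf_rank1_error_near_zero_and_increases_with_noise():
    rng = np.random.default_rng(0)
    u = rng.uniform(1, 2, size=(40, 1))
    v = rng.uniform(0, 1, size=(1, 20))
    X = pd.DataFrame(u @ v)
    X.columns = [f"g{j}" for j in X.columns]
    res, _ = programs.consensus_nmf(X, k_range=[1], n_restarts=3, seed=0)
    assert res[1].error < 1e-4
    noisy = X + rng.uniform(0, 0.3, size=X.shape)
    res2, _ = programs.consensus_nmf(noisy, k_range=[1], n_restarts=3, seed=0)
    assert res2[1].error > res[1].error


def test_consensus_nmf_selects_planted_k_and_recovers_modules():
    adata, blocks = synthetic.generate_planted_programs(seed=0)
    X = programs.prepare_nmf_input(adata, genes=list(adata.var_names))
    res, k = programs.consensus_nmf(X, k_range=range(2, 6), n_restarts=20,
                                    seed=0)
    assert k == 3
    for m in range(3):
        top = set(res[3].top_genes(m, 20))
        best = max(len(top & set(b)) / 20 for b in blocks)
        assert best >= 0.8
    # spectra rows are unit norm, usages nonnegative
    assert np.allclose(
        np.linalg.norm(res[3].spectra.to_numpy(), axis=1), 1.0, atol=1e-8
    )
    assert (res[3].usages.to_numpy() >= 0).all()


def test_consensus_nmf_input_validation():
    X = pd.DataFrame([[1.0, -0.5]])
    with pytest.raises(ValueError, match="nonnegative"):
        programs.consensus_nmf(X, k_range=[1], n_restarts=2)


# --- call_specific_modules --------------------------------------------------


def test_call_specific_modules_hand_table():
    usages = pd.DataFrame(
        {
            "m1": [10, 10, 1, 1, 1, 1, 1, 1],  # specific to cluster A
            "m2": [5, 5, 5, 5, 5, 5, 5, 5],  # uniform
            "m3": [8, 8, 1, 1, 5, 5, 1, 1],  # A-high but B at 5: fold < 2
        },
        index=[f"c{i}" for i in range(8)],
    )
    labels = pd.Series(list("AABBCCDD"), index=usages.index)
    got = programs.call_specific_modules(usages, labels, "A", fold=2.0)
    assert got == ["m1"]
    with pytest.raises(ValueError):
        programs.call_specific_modules(usages, labels, "Z")


# --- projection and aggregation ---------------------------------------------


def test_projection_requires_set_genes_present(normalized_dataset):
    adata, _, truth = normalized_dataset
    labels = truth["true_type"]
    with pytest.raises(ValueError, match="genes present"):
        programs.project_on_genesets(
            adata, [GeneSet("missing", [f"zz{i}" for i in range(20)])],
            labels, ["AER"], top_n=100,
        )


def test_aggregation_trivial_geometries():
    rng = np.random.default_rng(0)
    meso = rng.normal(0, 0.5, size=(40, 3))
    epi = rng.normal(20, 0.5, size=(40, 3))
    pcs = pd.DataFrame(np.vstack([meso, epi]),
                       index=[f"c{i}" for i in range(80)])
    lineage = pd.Series(["mesoderm"] * 40 + ["ectoderm"] * 40,
                        index=pcs.index)
    score, frac = programs.cross_lineage_aggregation(pcs, lineage, k=10)
    assert score == 0.0
    # mesodermal cells duplicated onto epithelial coordinates -> score 1
    pcs2 = pd.DataFrame(np.vstack([epi + rng.normal(0, 0.01, epi.shape), epi]),
                        index=pcs.index)
    score2, _ = programs.cross_lineage_aggregation(pcs2, lineage, k=10)
    assert score2 == 1.0


def test_aggregation_rotation_invariance():
    rng = np.random.default_rng(3)
    pcs = pd.DataFrame(rng.normal(size=(60, 4)),
                       index=[f"c{i}" for i in range(60)])
    lineage = pd.Series(["mesoderm"] * 30 + ["ectoderm"] * 30,
                        index=pcs.index)
    s1, f1 = programs.cross_lineage_aggregation(pcs, lineage, k=8)
    Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    rotated = pd.DataFrame(pcs.to_numpy() @ Q, index=pcs.index)
    s2, f2 = programs.cross_lineage_aggregation(rotated, lineage, k=8)
    assert s1 == s2
    assert np.allclose(f1.to_numpy(), f2.to_numpy())


def test_aggregation_validation():
    pcs = pd.DataFrame(np.zeros((5, 2)), index=[f"c{i}" for i in range(5)])
    lineage = pd.Series(["mesoderm"] * 5, index=pcs.index)
    with pytest.raises(ValueError, match="both lineages"):
        programs.cross_lineage_aggregation(pcs, lineage, k=2)
    lineage.iloc[0] = "ectoderm"
    with pytest.raises(ValueError, match="k="):
        programs.cross_lineage_aggregation(pcs, lineage, k=5)


# --- ORA --------------------------------------------------------------------


def test_ora_closed_form_values():
    universe = [f"g{i}" for i in range(20)]
    sets = {"s": universe[:5]}
    table = programs.ora_hypergeometric(universe[:5], sets, universe)
    assert table.loc["s", "p"] == pytest.approx(1 / math.comb(20, 5))
    # hits = set = universe -> p = 1
    t2 = programs.ora_hypergeometric(universe, {"all": universe}, universe)
    assert t2.loc["all", "p"] == pytest.approx(1.0)
    # zero overlap -> upper tail from 0 is 1
    t3 = programs.ora_hypergeometric(universe[:3], {"s": universe[10:15]},
                                     universe)
    assert t3.loc["s", "p"] == pytest.approx(1.0)


def test_ora_rejects_hits_outside_universe():
    with pytest.raises(ValueError):
        programs.ora_hypergeometric(["x"], {"s": ["a"]}, ["a", "b"])
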