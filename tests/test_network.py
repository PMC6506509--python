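"""Signed adjacency, TOM, module detection, eigengenes and edge export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from helpers import two_block_expression
from schet.errors import ValidationError
from schet.network import (
    ModuleSet,
    NetworkMatrices,
    detect_modules,
    eigengene_correlation,
    module_eigengenes,
    module_trait_significance,
    node_centrality,
    signed_adjacency,
    top_edges,
    topological_overlap,
)
from schet.normalize import NormalizedMatrix


def _nm(log_values, gene_ids=None):
    log_values = np.asarray(log_values, dtype=float)
    n_genes, n_cells = log_values.shape
    return NormalizedMatrix(
        values=np.maximum(2.0**log_values - 1, 0),
        log_values=log_values,
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        is_spikein=np.zeros(n_genes, dtype=bool),
        filter_mask=np.ones(n_genes, dtype=bool),
    )


def _net(adj, ids=None):
    adj = np.asarray(adj, dtype=float)
    ids = ids or [f"g{i}" for i in range(adj.shape[0])]
    return NetworkMatrices(adjacency=adj, connectivity=adj.sum(1) - 1,
                          beta=12.0, gene_ids=ids)


def test_signed_adjacency_boundary_values():
    """cor 1 -> a = 1; cor 0 -> 0.5^12 = 1/4096; cor -1 -> a = 0."""
    x = np.arange(10.0)
    rng = np.random.default_rng(0)
    z = rng.normal(size=10)
    z -= z.mean()
    z -= x.std() and (np.dot(z, x - x.mean()) / np.dot(x - x.mean(), x - x.mean())) * (x - x.mean())
    L = np.vstack([x, 2 * x + 3, -x, z])  # cor(x, 2x+3)=1, cor(x,-x)=-1, cor(x,z)=0
    nm = _nm(L)
    net = signed_adjacency(nm, np.arange(4), beta=12.0)
    A = net.adjacency
    assert np.isclose(A[0, 1], 1.0)
    assert np.isclose(A[0, 2], 0.0)
    assert np.isclose(A[0, 3], 0.5**12)
    assert np.isclose(0.5**12, 1 / 4096)


def test_adjacency_monotone_in_correlation():
    cors = np.linspace(-1, 1, 21)
    a = ((1 + cors) / 2) ** 12
    assert np.all(np.diff(a) > 0)


def test_zero_variance_gene_warns_and_zeroes():
    L = np.vstack([np.arange(6.0), np.full(6, 2.0), np.arange(6.0)[::-1]])
    with pytest.warns(UserWarning, match="zero-variance"):
        net = signed_adjacency(_nm(L), np.arange(3), beta=2.0)
    assert net.adjacency[0, 1] == 0.5**2  # cor treated as 0
    assert net.adjacency[1, 1] == 1.0


def test_tom_hand_oracle_three_nodes():
    """All pairwise a=0.5: k=1 each, TOM_12 = (0.25+0.5)/(1+1-0.5) = 0.5."""
    A = np.full((3, 3), 0.5)
    np.fill_diagonal(A, 1.0)
    tom = topological_overlap(_net(A))
    expected = (0.25 + 0.5) / (1 + 1 - 0.5)
    assert abs(tom[0, 1] - expected) < 1e-12
    assert abs(expected - 0.5) < 1e-12


def test_tom_zero_and_complete_graphs():
    Z = np.eye(3)
    tz = topological_overlap(_net(Z))
    assert np.allclose(tz[~np.eye(3, dtype=bool)], 0.0)
    C = np.ones((3, 3))
    tc = topological_overlap(_net(C))
    assert np.allclose(tc, 1.0)


def test_tom_symmetric_in_unit_interval():
    rng = np.random.default_rng(1)
    L = rng.normal(size=(30, 25))
    net = signed_adjacency(_nm(L), np.arange(30), beta=6.0)
    tom = topological_overlap(net)
    assert np.allclose(tom, tom.T)
    assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


def test_two_block_module_recovery():
    """Planted blocks (cor ~0.7) among 600 background genes: exactly 2
    modules, ARI >= 0.9.  Reduced seeds here; 10-seed run in acceptance."""
    for seed in range(2):
        X, labels = two_block_expression(seed)
        nm = _nm(X)
        net = signed_adjacency(nm, np.arange(len(labels)), beta=12.0)
        tom = topological_overlap(net)
        ms = detect_modules(tom, net.gene_ids, min_module_size=30, log_values=X)
        assert len(ms.module_names) == 2
        assert adjusted_rand_score(labels, list(ms.labels)) >= 0.9


def test_min_module_size_above_blocks_leaves_all_unassigned():
    X, labels = two_block_expression(3, block=20, background=100)
    nm = _nm(X)
    net = signed_adjacency(nm, np.arange(len(labels)), beta=12.0)
    tom = topological_overlap(net)
    with pytest.warns(UserWarning, match="unassigned"):
        ms = detect_modules(tom, net.gene_ids, min_module_size=50, log_values=X)
    assert (ms.labels == "unassigned").all()


def test_module_detection_invariant_to_gene_order():
    X, labels = two_block_expression(4, background=200)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(labels))
    nm1, nm2 = _nm(X), _nm(X[perm])
    t1 = topological_overlap(signed_adjacency(nm1, np.arange(len(labels)), 12.0))
    t2 = topological_overlap(signed_adjacency(nm2, np.arange(len(labels)), 12.0))
    ms1 = detect_modules(t1, nm1.gene_ids, min_module_size=30, log_values=X)
    ms2 = detect_modules(t2, nm2.gene_ids, min_module_size=30, log_values=X[perm])
    assert adjusted_rand_score(list(ms1.labels[perm]), list(ms2.labels)) == 1.0


def test_eigengene_of_two_perfectly_correlated_genes():
    x = np.arange(10.0)
    L = np.vstack([x, 3 * x + 1])
    nm = _nm(L)
    ms = ModuleSet(labels=np.array(["turquoise"] * 2, dtype=object),
                   gene_ids=nm.gene_ids)
    eig = module_eigengenes(nm, ms)
    r = np.corrcoef(eig["turquoise"], x)[0, 1]
    assert np.isclose(abs(r), 1.0)
    assert r > 0  # orientation: positive mean correlation with members


def test_eigengene_orientation_invariant_to_global_sign_flip():
    rng = np.random.default_rng(2)
    L = rng.normal(size=(8, 20)) + rng.normal(size=20)
    nm = _nm(L)
    ms = ModuleSet(labels=np.array(["turquoise"] * 8, dtype=object),
                   gene_ids=nm.gene_ids)
    e1 = module_eigengenes(nm, ms)["turquoise"].to_numpy()
    nm2 = _nm(-L)
    e2 = module_eigengenes(nm2, ms)["turquoise"].to_numpy()
    assert np.allclose(np.abs(np.corrcoef(e1, e2)[0, 1]), 1.0)


def test_module_trait_exact_indicator_and_null_uniform():
    rng = np.random.default_rng(3)
    n = 50
    labels = np.array([1] * 25 + [2] * 25)
    ind = (labels == 1).astype(float)
    eig = pd.DataFrame({"turquoise": (ind - ind.mean()) / np.linalg.norm(ind - ind.mean())})
    mt = module_trait_significance(eig, labels)
    assert np.isclose(abs(mt[("1", "r")].iloc[0]), 1.0)
    assert mt[("1", "p")].iloc[0] < 1e-30
    # null: independent noise eigengene, p uniform (KS at alpha = 0.01)
    ps = []
    for _ in range(1000):
        e = pd.DataFrame({"m": rng.normal(size=n)})
        ps.append(module_trait_significance(e, labels)[("1", "p")].iloc[0])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_module_trait_single_cell_group_missing():
    labels = np.array([1] * 9 + [2])
    eig = pd.DataFrame({"m": np.random.default_rng(4).normal(size=10)})
    mt = module_trait_significance(eig, labels)
    assert np.isnan(mt[("2", "p")].iloc[0])


def test_eigengene_correlation_self_and_requirements():
    rng = np.random.default_rng(5)
    eig = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
    cc = eigengene_correlation(eig)
    assert np.isclose(cc.loc["a", "a"], 1.0)
    with pytest.raises(ValidationError):
        eigengene_correlation(eig[["a"]])


def test_node_centrality_hand_sum():
    """3-gene module, pairwise a = {0.9, 0.5, 0.1}: kWithin = (1.4, 1.0, 0.6)."""
    A = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.1], [0.5, 0.1, 1.0]])
    net = _net(A)
    ms = ModuleSet(labels=np.array(["turquoise"] * 3, dtype=object),
                   gene_ids=net.gene_ids)
    df = node_centrality(net, ms)
    assert np.allclose(df["kwithin"].to_numpy(), [1.4, 1.0, 0.6])
    assert df["rank"].tolist() == [1, 2, 3]


def test_node_centrality_singleton_zero():
    A = np.eye(2)
    net = _net(A)
    ms = ModuleSet(labels=np.array(["turquoise", "blue"], dtype=object),
                   gene_ids=net.gene_ids)
    assert (node_centrality(net, ms)["kwithin"] == 0).all()


def test_top_edges_sorted_capped_and_tie_broken():
    A = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.1], [0.5, 0.1, 1.0]])
    net = _net(A)
    topological_overlap(net)
    all_edges = top_edges(net, n=100)
    assert len(all_edges) == 3  # 3 genes -> at most 3 edges
    w = all_edges["weight"].to_numpy()
    assert np.all(np.diff(w) <= 0)
    one = top_edges(net, n=1)
    assert len(one) == 1
    assert one["weight"].iloc[0] == w[0]
    # exact ties broken lexicographically
    net2 = _net(np.full((3, 3), 0.5) + np.eye(3) * 0.5)
    topological_overlap(net2)
    e = top_edges(net2, n=3)
    assert e[["source", "target"]].values.tolist() == [
        ["g0", "g1"], ["g0", "g2"], ["g1", "g2"]]
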