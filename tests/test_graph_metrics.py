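"""Topology metrics vs hand computations and a networkx oracle; null models."""

import numpy as np
import networkx as nx
import pytest

from neurograph.graph_metrics import (
    NullEnsembleConfig,
    auc_trapezoid,
    characteristic_path_length,
    clustering_coefficients,
    degree_centrality,
    global_efficiency,
    global_metrics,
    local_efficiency,
    mean_clustering,
    metric_curves,
    nodal_efficiency,
    rewire_null,
    shortest_path_lengths,
    small_world,
)
from neurograph.network_construction import ConnectivityMatrix, sparsity_grid


def complete(n):
    a = ~np.eye(n, dtype=bool)
    return a


def test_degree_centrality_hand_cases(make_adjacency):
    assert np.all(degree_centrality(complete(90)) == 89)
    path3 = make_adjacency(3, [(0, 1), (1, 2)])
    assert degree_centrality(path3).tolist() == [1, 2, 1]
    g5 = make_adjacency(5, [(0, 1), (0, 2), (1, 2), (2, 3)])
    assert degree_centrality(g5).tolist() == [2, 2, 3, 1, 0]


def test_clustering_hand_cases(make_adjacency):
    triangle = make_adjacency(3, [(0, 1), (1, 2), (0, 2)])
    assert np.allclose(clustering_coefficients(triangle), 1.0)
    assert mean_clustering(triangle) == 1.0
    star = make_adjacency(5, [(0, i) for i in range(1, 5)])
    assert np.all(clustering_coefficients(star) == 0.0)
    # K4 minus one edge: two degree-3 nodes have C=2/3, two degree-2 have C=1
    k4m = make_adjacency(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
    c = clustering_coefficients(k4m)
    assert c[0] == pytest.approx(2 / 3)
    assert c[1] == pytest.approx(2 / 3)
    assert c[2] == pytest.approx(1.0)
    assert c[3] == pytest.approx(1.0)
    assert mean_clustering(k4m) == pytest.approx(5 / 6)


def test_shortest_paths_hand_and_disconnected(make_adjacency):
    path3 = make_adjacency(3, [(0, 1), (1, 2)])
    d = shortest_path_lengths(path3)
    assert d[0, 2] == 2
    two_comp = make_adjacency(4, [(0, 1), (2, 3)])
    d = shortest_path_lengths(two_comp)
    assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


def test_shortest_paths_agree_with_floyd_warshall(random_graphs):
    for a in random_graphs(50, max_n=20, seed=42):
        n = a.shape[0]
        # brute-force Floyd-Warshall oracle
        d = np.where(a, 1.0, np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(n):
            d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
        assert np.array_equal(shortest_path_lengths(a), d)


def test_characteristic_path_length_conventions(make_adjacency):
    assert characteristic_path_length(complete(5))[0] == 1.0
    path3 = make_adjacency(3, [(0, 1), (1, 2)])
    lp, cf = characteristic_path_length(path3)
    assert lp == pytest.approx(4 / 3)
    assert cf == 1.0
    # isolated node leaves Lp unchanged, lowers the connected fraction
    plus_iso = make_adjacency(4, [(0, 1), (1, 2)])
    lp2, cf2 = characteristic_path_length(plus_iso)
    assert lp2 == pytest.approx(4 / 3)
    assert cf2 < 1.0
    with pytest.raises(ValueError, match="empty"):
        characteristic_path_length(np.zeros((4, 4), dtype=bool))


def test_efficiency_hand_cases(make_adjacency):
    assert global_efficiency(complete(6)) == 1.0
    assert np.allclose(nodal_efficiency(complete(6)), 1.0)
    path3 = make_adjacency(3, [(0, 1), (1, 2)])
    assert global_efficiency(path3) == pytest.approx(5 / 6)
    assert global_efficiency(np.zeros((5, 5), dtype=bool)) == 0.0
    triangle = make_adjacency(3, [(0, 1), (1, 2), (0, 2)])
    assert local_efficiency(triangle) == 1.0
    star = make_adjacency(5, [(0, i) for i in range(1, 5)])
    assert local_efficiency(star) == 0.0


def test_metrics_match_networkx_oracle(random_graphs):
    """Cp, Lp, Eg, Eloc, Ne, Dc agree with networkx to 1e-9 on 100 graphs."""
    for a in random_graphs(100, max_n=30, seed=7):
        g = nx.from_numpy_array(a.astype(int))
        n = a.shape[0]
        assert np.allclose(degree_centrality(a), [g.degree(i) for i in range(n)])
        assert np.allclose(
            clustering_coefficients(a), [nx.clustering(g, i) for i in range(n)], atol=1e-9
        )
        assert abs(global_efficiency(a) - nx.global_efficiency(g)) < 1e-9
        assert abs(local_efficiency(a) - nx.local_efficiency(g)) < 1e-9
        # Lp over finite pairs and Ne from BFS distances
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        finite = [d for i, row in lengths.items() for j, d in row.items() if i != j]
        if finite:
            lp, _ = characteristic_path_length(a)
            assert abs(lp - np.mean(finite)) < 1e-9
        ne = nodal_efficiency(a)
        for i in range(n):
            inv = [1 / d for j, d in lengths[i].items() if j != i]
            assert abs(ne[i] - sum(inv) / (n - 1)) < 1e-9


def test_rewiring_preserves_degrees_and_edges(random_graphs):
    for a in random_graphs(5, max_n=30, seed=3):
        if a.sum() < 4:
            continue
        cfg = NullEnsembleConfig(n_nulls=10, swaps_per_edge=10, seed=5)
        for null in rewire_null(a, cfg):
            assert np.array_equal(degree_centrality(null), degree_centrality(a))
            assert null.sum() == a.sum()
            assert not null.diagonal().any()


def test_rewiring_is_seeded_deterministic():
    rng = np.random.default_rng(0)
    a = rng.random((40, 40)) < 0.2
    a = np.triu(a, 1)
    a = a | a.T
    cfg = NullEnsembleConfig(n_nulls=3, seed=9)
    n1 = rewire_null(a, cfg)
    n2 = rewire_null(a, cfg)
    assert all(np.array_equal(x, y) for x, y in zip(n1, n2))


def test_rewiring_degenerate_graph_returns_copies():
    a = np.zeros((5, 5), dtype=bool)
    a[0, 1] = a[1, 0] = True
    with pytest.warns(UserWarning, match="fewer than 2 edges"):
        nulls = rewire_null(a, NullEnsembleConfig(n_nulls=3, seed=0))
    assert all(np.array_equal(x, a) for x in nulls)


def test_rewiring_er_graph_changes_nothing_systematically():
    """Randomizing an already-random graph: <Cp_rand> within 3 MC SE of Cp."""
    rng = np.random.default_rng(12)
    a = rng.random((90, 90)) < 0.2
    a = np.triu(a, 1)
    a = a | a.T
    cp_obs = mean_clustering(a)
    cps = [mean_clustering(x) for x in rewire_null(a, NullEnsembleConfig(n_nulls=50, seed=1))]
    se = np.std(cps, ddof=1) / np.sqrt(len(cps))
    assert abs(np.mean(cps) - cp_obs) < 3 * se + 1e-3


def test_small_world_self_normalization_and_lattice():
    rng = np.random.default_rng(4)
    a = rng.random((90, 90)) < 0.2
    a = np.triu(a, 1)
    a = a | a.T
    sw = small_world(a, NullEnsembleConfig(n_nulls=30, seed=2))
    assert sw.gamma == pytest.approx(1.0, abs=0.1)
    assert sw.lam == pytest.approx(1.0, abs=0.1)
    assert sw.sigma == pytest.approx(1.0, abs=0.1)
    assert sw.sigma == sw.gamma / sw.lam  # definitional identity
    # ring lattice, k=10 neighbors: clustering far above randomized
    ring = np.zeros((90, 90), dtype=bool)
    for i in range(90):
        for off in range(1, 6):
            j = (i + off) % 90
            ring[i, j] = ring[j, i] = True
    sw_ring = small_world(ring, NullEnsembleConfig(n_nulls=20, seed=3))
    assert sw_ring.gamma > 1


def test_global_metrics_ranges(random_graphs):
    for a in random_graphs(10, max_n=25, seed=11):
        if not a.any():
            continue
        gm = global_metrics(a)
        assert 0 <= gm.Cp <= 1 and 0 <= gm.Eg <= 1 and 0 <= gm.Eloc <= 1
        ne = nodal_efficiency(a)
        assert np.all((ne >= 0) & (ne <= 1))
        dc = degree_centrality(a)
        assert dc.sum() == a.sum()  # handshake: sum(Dc) = 2|E|


def test_auc_of_constant_and_identity_curves():
    grid = sparsity_grid("functional_subject")
    assert auc_trapezoid(np.full(grid.size, 2.0), grid) == pytest.approx(2.0 * 0.3)
    assert auc_trapezoid(grid.copy(), grid) == pytest.approx((0.4**2 - 0.1**2) / 2)


def test_metric_curves_assemble_and_dc_monotone(node_names):
    rng = np.random.default_rng(5)
    w = rng.uniform(0.01, 1.0, size=(90, 90))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    cm = ConnectivityMatrix(weights=w, node_labels=node_names, kind="functional_subject")
    grid = sparsity_grid("functional_subject")[::6]
    curve = metric_curves(cm, grid)
    assert list(curve.global_curves.index) == list(grid)
    dc = curve.nodal_curves["Dc"]
    assert np.all(np.diff(dc, axis=0) >= 0)  # edges only added with sparsity
    assert curve.auc["Cp"] == pytest.approx(
        auc_trapezoid(curve.global_curves["Cp"].to_numpy(), grid)
    )
    assert curve.nodal_auc["Ne"].shape == (90,)
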