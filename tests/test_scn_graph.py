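"""Covariance networks, density thresholding, graph measures, cartography."""

import numpy as np
import pytest

from conftest import make_table, null_config
from oracles import (
    brute_degree,
    brute_mean_distance,
    brute_modularity,
    brute_transitivity,
    random_graph,
)
from scnkit.scn_graph import (
    CovarianceMatrix,
    ThresholdedNetwork,
    build_covariance,
    cartography,
    degree,
    edge_count_at_density,
    mean_distance,
    modularity,
    threshold_at_density,
    transitivity,
    walktrap_communities,
)
from scnkit.synthetic_data import generate_cohort


def net_from_adj(adj, names=None) -> ThresholdedNetwork:
    n = len(adj)
    names = names or tuple(f"n{i:02d}" for i in range(n))
    dens = adj.sum() / (n * (n - 1)) if n > 1 else 1.0
    return ThresholdedNetwork(density=max(dens, 1e-6), regions=names, adjacency=adj)


def clique_pair(k=3) -> np.ndarray:
    adj = np.zeros((2 * k, 2 * k), dtype=np.int8)
    adj[:k, :k] = 1
    adj[k:, k:] = 1
    np.fill_diagonal(adj, 0)
    return adj


# ------------------------------------------------------------- covariance


def test_identical_regions_give_unit_correlation(rng):
    tbv = rng.normal(100, 10, 8)
    base = rng.normal(10, 1, 8) + 5
    t = make_table({"a": base, "b": 2 * base, "c": np.abs(rng.normal(8, 1, 8)) + 2},
                   tbv, ["g"] * 8, group_order=("g",))
    cov = build_covariance(t, "g")
    i, j = t.regions.index("a"), t.regions.index("b")
    assert cov.r[i, j] == pytest.approx(1.0)


def test_negative_correlations_zeroed(rng):
    tbv = rng.normal(100, 10, 10)
    base = rng.normal(0, 1, 10)
    t = make_table({"a": 10 + base, "b": 10 - base, "c": np.abs(rng.normal(8, 1, 10)) + 2},
                   tbv, ["g"] * 10, group_order=("g",))
    cov = build_covariance(t, "g")
    i, j = t.regions.index("a"), t.regions.index("b")
    assert cov.r[i, j] == 0.0
    assert np.diag(cov.r).sum() == 0.0


def test_block_structure_survives_into_covariance():
    cfg = null_config(
        seed=21, n_per_group=200, groups=("young",),
        within_community_r=0.8, between_community_r=0.1,
        community_assignment={r: i % 4 for i, r in enumerate(
            tuple(f"region{i:02d}" for i in range(32)))},
        region_names=tuple(f"region{i:02d}" for i in range(32)),
        behavior_link={},
    )
    cohort = generate_cohort(cfg)
    cov = build_covariance(cohort.volumes, "young")
    comm = np.array([i % 4 for i in range(32)])
    same = comm[:, None] == comm[None, :]
    np.fill_diagonal(same, False)
    assert cov.r[same].mean() > cov.r[~same & ~np.eye(32, dtype=bool)].mean()


def test_zero_variance_region_errors(rng):
    t = make_table({"a": [5.0] * 6, "b": np.abs(rng.normal(8, 1, 6)) + 2},
                   [100, 100, 100, 100, 100, 101], ["g"] * 6, group_order=("g",))
    # 'a' is constant -> zero residual variance once tbv is nearly constant
    with pytest.raises(ValueError, match="zero residual variance"):
        build_covariance(t, "g")


def test_small_group_errors():
    t = make_table({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]},
                   [10, 20, 30], ["g"] * 3, group_order=("g",))
    with pytest.raises(ValueError, match="fewer than 4"):
        build_covariance(t, "g")


# ------------------------------------------------------------ thresholding


def cov_from_matrix(r, names=None) -> CovarianceMatrix:
    n = len(r)
    names = names or tuple(f"n{i:02d}" for i in range(n))
    return CovarianceMatrix(group="g", regions=names, r=r)


def test_full_density_complete_graph(rng):
    r = rng.random((32, 32)) * 0.5 + 0.25
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0)
    net = threshold_at_density(cov_from_matrix(r), 1.0)
    assert net.n_edges == 496


def test_edge_count_rounding():
    assert edge_count_at_density(0.05, 32) == 25  # round(24.8)
    assert edge_count_at_density(0.40, 32) == 198  # round(198.4)
    assert edge_count_at_density(0.25, 32) == 124


def test_shortfall_warns_and_keeps_all_positive(rng, caplog):
    r = np.zeros((32, 32))
    idx = [(0, i) for i in range(1, 11)]
    for i, j in idx:
        r[i, j] = r[j, i] = 0.5
    with caplog.at_level("WARNING", logger="scnkit.scn_graph"):
        net = threshold_at_density(cov_from_matrix(r), 0.05)  # requests 25
    assert net.n_edges == 10
    assert net.shortfall
    assert "only 10 positive correlations" in caplog.text


def test_threshold_monotone_nesting(rng):
    r = rng.random((32, 32))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0)
    cov = cov_from_matrix(r)
    prev = set()
    for d in (0.05, 0.10, 0.20, 0.30, 0.40):
        edges = set(threshold_at_density(cov, d).edges)
        assert prev <= edges
        prev = edges


def test_threshold_tie_break_lexicographic():
    r = np.full((4, 4), 0.5)
    np.fill_diagonal(r, 0)
    net = threshold_at_density(cov_from_matrix(r, ("b", "d", "a", "c")), 2 / 6)
    # lexicographic name pairs: (a,b) then (a,c); edges report in index order
    assert set(net.edges) == {("b", "a"), ("a", "c")}


# ---------------------------------------------------------- graph metrics


def test_degree_hand_cases():
    tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
    assert degree(net_from_adj(tri)).tolist() == [2, 2, 2]
    star = np.zeros((4, 4), dtype=np.int8)
    star[0, 1:] = star[1:, 0] = 1
    assert degree(net_from_adj(star)).tolist() == [3, 1, 1, 1]


def test_mean_distance_hand_cases():
    full = np.ones((5, 5), dtype=np.int8) - np.eye(5, dtype=np.int8)
    assert mean_distance(net_from_adj(full)) == pytest.approx(1.0)
    path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
    assert mean_distance(net_from_adj(path)) == pytest.approx(4 / 3)
    two_edges = np.zeros((4, 4), dtype=np.int8)
    two_edges[0, 1] = two_edges[1, 0] = two_edges[2, 3] = two_edges[3, 2] = 1
    assert mean_distance(net_from_adj(two_edges)) == pytest.approx(1.0)
    assert mean_distance(net_from_adj(np.zeros((3, 3), dtype=np.int8))) is None


def test_transitivity_hand_cases():
    k4 = np.ones((4, 4), dtype=np.int8) - np.eye(4, dtype=np.int8)
    assert transitivity(net_from_adj(k4)) == pytest.approx(1.0)
    star = np.zeros((4, 4), dtype=np.int8)
    star[0, 1:] = star[1:, 0] = 1
    assert transitivity(net_from_adj(star)) == 0.0


def test_metrics_match_brute_force_on_random_graphs(rng):
    for _ in range(40):
        n = int(rng.integers(5, 33))
        adj = random_graph(rng, n, float(rng.uniform(0.05, 0.5)))
        net = net_from_adj(adj)
        assert degree(net).tolist() == brute_degree(adj)
        assert transitivity(net) == pytest.approx(brute_transitivity(adj), abs=1e-12)
        md, bmd = mean_distance(net), brute_mean_distance(adj)
        if bmd is None:
            assert md is None
        else:
            assert md == pytest.approx(bmd, abs=1e-12)
        membership = rng.integers(0, 4, n).tolist()
        q, bq = modularity(net, membership), brute_modularity(adj, membership)
        if bq is None:
            assert q is None
        else:
            assert q == pytest.approx(bq, abs=1e-12)


def test_metrics_invariant_under_relabeling(rng):
    adj = random_graph(rng, 20, 0.2)
    net = net_from_adj(adj)
    perm = rng.permutation(20)
    adj_p = adj[np.ix_(perm, perm)]
    net_p = net_from_adj(adj_p)
    assert transitivity(net) == pytest.approx(transitivity(net_p), abs=1e-12)
    assert mean_distance(net) == pytest.approx(mean_distance(net_p), abs=1e-12)
    assert sorted(degree(net)) == sorted(degree(net_p))
    membership = rng.integers(0, 3, 20)
    assert modularity(net, membership.tolist()) == pytest.approx(
        modularity(net_p, membership[perm].tolist()), abs=1e-12
    )


# ------------------------------------------------------------- communities


def test_walktrap_two_triangles():
    res = walktrap_communities(net_from_adj(clique_pair(3)))
    assert len(set(res.membership)) == 2
    assert res.membership[:3] != res.membership[3:]
    assert res.modularity == pytest.approx(0.5)


def test_walktrap_complete_graph_single_community():
    full = np.ones((6, 6), dtype=np.int8) - np.eye(6, dtype=np.int8)
    res = walktrap_communities(net_from_adj(full))
    assert len(set(res.membership)) == 1
    assert res.modularity == pytest.approx(0.0)


def test_walktrap_empty_network_singletons():
    res = walktrap_communities(net_from_adj(np.zeros((5, 5), dtype=np.int8)))
    assert len(set(res.membership)) == 5
    assert res.modularity == 0.0
    assert "empty" in res.note


def test_walktrap_never_below_trivial_partition(rng):
    for _ in range(20):
        adj = random_graph(rng, 16, 0.2)
        net = net_from_adj(adj)
        if net.n_edges == 0:
            continue
        res = walktrap_communities(net)
        q_trivial = modularity(net, [0] * 16)
        assert res.modularity >= q_trivial - 1e-12


def test_modularity_two_cliques_true_partition():
    net = net_from_adj(clique_pair(4))
    assert modularity(net, [0] * 4 + [1] * 4) == pytest.approx(0.5)
    assert modularity(net, [0] * 8) == pytest.approx(0.0)


# ------------------------------------------------------------- cartography


def test_participation_hand_values():
    # node 0 connects 2/2 across two communities -> P = 0.5
    adj = np.zeros((5, 5), dtype=np.int8)
    for j in (1, 2, 3, 4):
        adj[0, j] = adj[j, 0] = 1
    membership = [0, 0, 0, 1, 1]
    res = cartography(net_from_adj(adj), membership)
    assert res.participation[0] == pytest.approx(0.5)
    # a node with all edges inside its own community -> P = 0
    adj2 = clique_pair(3)
    res2 = cartography(net_from_adj(adj2), [0, 0, 0, 1, 1, 1])
    assert np.allclose(res2.participation, 0.0)


def test_z_scores_standardized_within_communities(rng):
    adj = random_graph(rng, 16, 0.3)
    membership = [0] * 8 + [1] * 8
    res = cartography(net_from_adj(adj), membership)
    for c in (0, 1):
        z = res.z_within[np.array(membership) == c]
        if z.std() > 0:
            assert abs(z.mean()) < 1e-10
            assert z.std() == pytest.approx(1.0)


def test_clique_bridge_cartography():
    """Two K5s joined by a bridge node with 2 links into each clique."""
    n = 11
    adj = np.zeros((n, n), dtype=np.int8)
    adj[:5, :5] = 1
    adj[5:10, 5:10] = 1
    np.fill_diagonal(adj, 0)
    bridge = 10
    for j in (0, 1, 5, 6):
        adj[bridge, j] = adj[j, bridge] = 1
    membership = [0] * 5 + [1] * 5 + [0]
    res = cartography(net_from_adj(adj), membership, z_hub_min=0.5, p_connector_min=0.3)
    assert np.argmax(res.participation) == bridge
    assert res.participation[bridge] == pytest.approx(0.5)
    # in each clique, the bridge-adjacent members carry the highest z
    z = res.z_within
    assert {int(np.argmax(z[:5]))} <= {0, 1}
    assert 5 + int(np.argmax(z[5:10])) in {5, 6}


def test_planted_blocks_recovered_once():
    cfg = null_config(
        seed=33, n_per_group=200, groups=("young",),
        within_community_r=0.8, between_community_r=0.1,
        community_assignment={f"region{i:02d}": i % 4 for i in range(32)},
        region_names=tuple(f"region{i:02d}" for i in range(32)),
    )
    cohort = generate_cohort(cfg)
    cov = build_covariance(cohort.volumes, "young")
    net = threshold_at_density(cov, 0.20)
    res = walktrap_communities(net)
    from sklearn.metrics import adjusted_rand_score

    truth = [i % 4 for i in range(32)]
    assert adjusted_rand_score(truth, list(res.membership)) > 0.8
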