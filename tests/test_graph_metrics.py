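"""Graph metrics against brute-force and independent-library oracles."""
import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from connebm import WeightedConnectome, community_partition, normalize_weights
from connebm.connectome import weights_to_lengths
from connebm.errors import InvalidConnectomeError
from connebm.graph_metrics import (
    betweenness,
    clustering_coefficient,
    degree_zscore,
    eccentricity,
    eigenvector_centrality,
    global_metrics,
    local_efficiency,
    modularity,
    node_degree,
    node_metric_table,
    node_strength,
    pagerank_centrality,
    participation_coefficient,
    shortest_path_matrix,
)
import oracles


def _conn(W):
    return WeightedConnectome([f"n{i}" for i in range(len(W))], np.asarray(W, float))


# ---------------------------------------------------------------------------
# hand-checkable cases
# ---------------------------------------------------------------------------

def test_degree_strength_on_complete_star_isolated():
    W = np.full((4, 4), 0.5)
    np.fill_diagonal(W, 0.0)
    c = _conn(W)
    np.testing.assert_array_equal(node_degree(c), [3, 3, 3, 3])
    np.testing.assert_allclose(node_strength(c), [1.5] * 4)
    star = np.zeros((6, 6))
    star[0, 1:] = star[1:, 0] = 1.0
    cs = _conn(star)
    assert node_degree(cs)[0] == 5 and node_strength(cs)[0] == 5
    iso = np.zeros((3, 3))
    iso[0, 1] = iso[1, 0] = 1.0
    ci = _conn(iso)
    assert node_degree(ci)[2] == 0 and node_strength(ci)[2] == 0


def test_shortest_paths_prefer_multi_hop_route():
    # direct edge of length 5 vs 1+1 through the middle node
    L = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 1.0], [5.0, 1.0, 0.0]])
    D = shortest_path_matrix(L)
    assert D[0, 2] == pytest.approx(2.0)
    # 3-node line: end-to-end distance is the sum
    L2 = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]], float)
    assert shortest_path_matrix(L2)[0, 2] == pytest.approx(2.0)
    # isolated node keeps +inf everywhere
    L3 = np.full((3, 3), np.inf)
    np.fill_diagonal(L3, 0)
    L3[0, 1] = L3[1, 0] = 1.0
    D3 = shortest_path_matrix(L3)
    assert np.isinf(D3[2, 0]) and np.isinf(D3[2, 1])


def test_louvain_separates_two_cliques(two_cliques):
    part = community_partition(two_cliques, seed=0)
    a = part.assignment
    assert len(set(a[:5])) == 1 and len(set(a[5:])) == 1 and a[0] != a[9]
    # exhaustive check over all 2-set partitions: the clique split is optimal
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=9):
        cand = np.array([0, *bits])
        best = max(best, modularity(two_cliques.weights, cand))
    assert part.modularity == pytest.approx(best, abs=1e-12)


def test_louvain_uniform_complete_graph_single_module():
    W = np.ones((6, 6)) - np.eye(6)
    part = community_partition(_conn(W), seed=1)
    assert part.n_modules == 1
    assert part.modularity == pytest.approx(0.0, abs=1e-12)


def test_louvain_deterministic_under_seed(two_cliques):
    a = community_partition(two_cliques, seed=42).assignment
    b = community_partition(two_cliques, seed=42).assignment
    np.testing.assert_array_equal(a, b)


def test_degree_zscore_hand_case():
    # one module of 4 nodes with within-degrees {3,1,1,1}: hub z = 1.5
    W = np.zeros((4, 4))
    W[0, 1:] = W[1:, 0] = 1.0
    c = _conn(W)
    from connebm.graph_metrics import ModulePartition

    part = ModulePartition(assignment=np.zeros(4, dtype=int), modularity=0.0)
    z = degree_zscore(c, part)
    assert z[0] == pytest.approx(1.5)
    # equal within-degree -> all zero; singleton module -> zero
    ring = np.roll(np.eye(4), 1, axis=1) + np.roll(np.eye(4), -1, axis=1)
    zr = degree_zscore(_conn(ring), part)
    np.testing.assert_allclose(zr, 0.0)
    single = ModulePartition(assignment=np.arange(4), modularity=0.0)
    np.testing.assert_allclose(degree_zscore(c, single), 0.0)


def test_participation_closed_forms():
    from connebm.graph_metrics import ModulePartition

    # node 0 splits its strength equally across two modules -> P = 0.5
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 1.0
    W[0, 2] = W[2, 0] = 1.0
    part = ModulePartition(assignment=np.array([0, 0, 1]), modularity=0.0)
    P = participation_coefficient(_conn(W), part)
    assert P[0] == pytest.approx(0.5)
    assert P[1] == pytest.approx(0.0)  # all strength inside own module
    W2 = np.zeros((3, 3))
    W2[0, 1] = W2[1, 0] = 1.0
    assert participation_coefficient(_conn(W2), part)[2] == 0.0  # isolated


def test_betweenness_path_complete_and_star():
    line = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    nbc, _ = betweenness(weights_to_lengths(_conn(line)))
    np.testing.assert_allclose(nbc, [0, 1, 0])
    comp = np.ones((5, 5)) - np.eye(5)
    nbc2, ebc2 = betweenness(weights_to_lengths(_conn(comp)))
    np.testing.assert_allclose(nbc2, 0.0)
    np.testing.assert_allclose(ebc2, 4.0)  # each incident edge carries its own pair
    star = np.zeros((6, 6))
    star[0, 1:] = star[1:, 0] = 1.0
    nbc3, _ = betweenness(weights_to_lengths(_conn(star)))
    assert nbc3[0] == pytest.approx(10.0)  # C(5,2) leaf pairs


def test_clustering_triangle_values():
    tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
    np.testing.assert_allclose(clustering_coefficient(_conn(tri)), 1.0)
    weak = np.array([[0, 1, 1], [1, 0, 0.125], [1, 0.125, 0]])
    C = clustering_coefficient(_conn(weak))
    # node 0 sits opposite the weak edge: cube-root triangle intensity 0.5
    assert C[0] == pytest.approx(0.5)
    star = np.zeros((5, 5))
    star[0, 1:] = star[1:, 0] = 1.0
    np.testing.assert_allclose(clustering_coefficient(_conn(star)), 0.0)


def test_local_efficiency_triangle_and_degenerate():
    tri = np.ones((3, 3)) - np.eye(3)
    np.testing.assert_allclose(local_efficiency(_conn(tri)), 1.0)
    line = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    eff = local_efficiency(_conn(line))
    assert eff[0] == 0.0  # single neighbor


def test_eccentricity_four_cycle():
    ring = np.roll(np.eye(4), 1, axis=1) + np.roll(np.eye(4), -1, axis=1)
    D = shortest_path_matrix(weights_to_lengths(_conn(ring)))
    np.testing.assert_allclose(eccentricity(D), 2.0)


def test_pagerank_uniform_cases():
    ring = np.roll(np.eye(5), 1, axis=1) + np.roll(np.eye(5), -1, axis=1)
    np.testing.assert_allclose(pagerank_centrality(_conn(ring)), 0.2, atol=1e-10)
    rng = np.random.default_rng(0)
    W = oracles.random_normalized_graph(rng)
    c = _conn(W)
    np.testing.assert_allclose(
        pagerank_centrality(c, damping=0.0), 1.0 / len(W), atol=1e-12
    )


def test_eigenvector_symmetric_pair():
    W = np.array([[0, 1.0], [1.0, 0]])
    v = eigenvector_centrality(_conn(W))
    np.testing.assert_allclose(v, [1.0, 1.0])


def test_global_metrics_trivial_cases(triangle):
    gm = global_metrics(triangle)
    assert gm.density == 1.0
    assert gm.transitivity == pytest.approx(1.0)
    empty = _conn(np.zeros((4, 4)))
    gme = global_metrics(empty)
    assert gme.density == 0.0 and gme.global_efficiency == 0.0
    with pytest.raises(InvalidConnectomeError):
        global_metrics(_conn(np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# oracle equivalence on random graphs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(12))
def test_all_metrics_match_oracles_on_random_graphs(seed):
    """Every nodal and global metric agrees with the independent oracles."""
    rng = np.random.default_rng(1000 + seed)
    W = oracles.random_normalized_graph(rng)
    c = _conn(W)
    part = community_partition(c, seed=seed)
    tbl = node_metric_table(c, partition=part)
    L = weights_to_lengths(c)

    dist, node_bc, edge_bc = oracles.enumerate_geodesics(L)
    np.testing.assert_allclose(shortest_path_matrix(L), dist, atol=1e-8)
    deg, stren = oracles.degree_strength(W)
    np.testing.assert_allclose(tbl["degree"], deg, atol=1e-8)
    np.testing.assert_allclose(tbl["strength"], stren, atol=1e-8)
    np.testing.assert_allclose(
        tbl["degree_zscore"], oracles.within_module_degree_z(W, part.assignment),
        atol=1e-8,
    )
    np.testing.assert_allclose(
        tbl["participation_coef"], oracles.participation(W, part.assignment), atol=1e-8
    )
    np.testing.assert_allclose(tbl["node_betweenness"], node_bc, atol=1e-8)
    np.testing.assert_allclose(tbl["edge_betweenness_nodal"], edge_bc, atol=1e-8)
    np.testing.assert_allclose(
        tbl["local_efficiency"], oracles.local_efficiency_brute(W), atol=1e-8
    )
    cpl, ecc = oracles.nodal_path_and_eccentricity(dist)
    np.testing.assert_allclose(tbl["char_path_length"], cpl, atol=1e-8)
    np.testing.assert_allclose(tbl["eccentricity"], ecc, atol=1e-8)
    np.testing.assert_allclose(
        tbl["clustering_coef"], oracles.onnela_clustering(W), atol=1e-8
    )
    np.testing.assert_allclose(
        tbl["eigenvector_centrality"], oracles.eigvec_centrality_dense(W), atol=1e-8
    )
    np.testing.assert_allclose(
        tbl["pagerank_centrality"], oracles.pagerank_dense(W), atol=1e-8
    )
    gm = global_metrics(c)
    density, eff, trans, assort = oracles.global_metrics_brute(W, dist)
    assert gm.density == pytest.approx(density, abs=1e-8)
    assert gm.global_efficiency == pytest.approx(eff, abs=1e-8)
    assert gm.transitivity == pytest.approx(trans, abs=1e-8)
    if np.isnan(assort):
        assert np.isnan(gm.assortativity)
    else:
        assert gm.assortativity == pytest.approx(assort, abs=1e-8)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

@given(scale=st.floats(min_value=0.1, max_value=50.0), seed=st.integers(0, 50))
def test_scale_invariance_after_normalization(scale, seed):
    """Rescaling all weights then renormalizing leaves every metric unchanged."""
    rng = np.random.default_rng(seed)
    W = oracles.random_normalized_graph(rng, n_min=5, n_max=7)
    c1 = normalize_weights(_conn(W))
    c2 = normalize_weights(_conn(W * scale))
    t1 = node_metric_table(c1, seed=0)
    t2 = node_metric_table(c2, seed=0)
    np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-9)


@given(seed=st.integers(0, 50))
def test_permutation_equivariance(seed):
    """Relabeling nodes permutes every per-node metric identically."""
    rng = np.random.default_rng(seed)
    W = oracles.random_normalized_graph(rng, n_min=5, n_max=7)
    n = len(W)
    perm = rng.permutation(n)
    Wp = W[np.ix_(perm, perm)]
    part = community_partition(_conn(W), seed=0)
    from connebm.graph_metrics import ModulePartition

    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    part_p = ModulePartition(part.assignment[perm], part.modularity)
    t1 = node_metric_table(_conn(W), partition=part).to_numpy()
    t2 = node_metric_table(_conn(Wp), partition=part_p).to_numpy()
    np.testing.assert_allclose(t2, t1[perm], atol=1e-9)


@given(seed=st.integers(0, 100))
def test_pagerank_sums_to_one(seed):
    rng = np.random.default_rng(seed)
    W = oracles.random_normalized_graph(rng, n_min=4, n_max=8)
    r = pagerank_centrality(_conn(W))
    assert abs(r.sum() - 1.0) < 1e-10
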