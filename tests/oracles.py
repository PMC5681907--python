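"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: exhaustive simple-path enumeration for
distances and betweenness, direct stage-sum evaluation for the EBM
likelihood, closed-form loops for the module-based and triangle-based
metrics, dense linear algebra for the spectral centralities, and networkx
for clustering/assortativity. None of it shares code with connebm.
"""
from __future__ import annotations

import math
from statistics import stdev

import networkx as nx
import numpy as np

TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# exhaustive geodesics
# ---------------------------------------------------------------------------

def enumerate_geodesics(L: np.ndarray):
    """Distances, node betweenness and nodal edge betweenness by enumerating
    every simple path (feasible for <= 8 nodes)."""
    n = L.shape[0]
    adj = [
        [w for w in range(n) if w != v and np.isfinite(L[v, w])] for v in range(n)
    ]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    node_bc = np.zeros(n)
    edge_bc = np.zeros((n, n))
    for s in range(n):
        for t in range(s + 1, n):
            paths: list[tuple[float, tuple[int, ...]]] = []

            def dfs(v, length, path):
                if v == t:
                    paths.append((length, tuple(path)))
                    return
                for w in adj[v]:
                    if w not in path:
                        path.append(w)
                        dfs(w, length + L[v, w], path)
                        path.pop()

            dfs(s, 0.0, [s])
            if not paths:
                continue
            best = min(p[0] for p in paths)
            dist[s, t] = dist[t, s] = best
            geo = [p for length, p in paths if length <= best + TIE_TOL]
            share = 1.0 / len(geo)
            for p in geo:
                for v in p[1:-1]:
                    node_bc[v] += share
                for a, b in zip(p[:-1], p[1:]):
                    edge_bc[a, b] += share
                    edge_bc[b, a] += share
    # edge_bc holds each edge's pair-once betweenness mirrored across the
    # diagonal, so a row sum counts each incident edge exactly once
    return dist, node_bc, edge_bc.sum(axis=1)


# ---------------------------------------------------------------------------
# nodal metrics from definitions
# ---------------------------------------------------------------------------

def degree_strength(W):
    return (W > 0).sum(axis=1).astype(float), W.sum(axis=1)


def within_module_degree_z(W, assignment):
    n = len(W)
    z = np.zeros(n)
    for m in set(assignment):
        idx = [i for i in range(n) if assignment[i] == m]
        ks = [sum(1 for j in idx if j != i and W[i, j] > 0) for i in idx]
        if len(idx) > 1 and len(set(ks)) > 1:
            mu = sum(ks) / len(ks)
            sd = stdev(ks)
            for pos, i in enumerate(idx):
                z[i] = (ks[pos] - mu) / sd
    return z


def participation(W, assignment):
    n = len(W)
    P = np.zeros(n)
    for i in range(n):
        s_i = W[i].sum()
        if s_i == 0:
            continue
        acc = 0.0
        for m in set(assignment):
            s_im = sum(W[i, j] for j in range(n) if assignment[j] == m)
            acc += (s_im / s_i) ** 2
        P[i] = 1.0 - acc
    return P


def local_efficiency_brute(W):
    n = len(W)
    out = np.zeros(n)
    for i in range(n):
        V = [j for j in range(n) if W[i, j] > 0]
        k = len(V)
        if k < 2:
            continue
        sub = np.full((k, k), np.inf)
        np.fill_diagonal(sub, 0.0)
        for a in range(k):
            for b in range(k):
                if a != b and W[V[a], V[b]] > 0:
                    sub[a, b] = W[V[a], V[b]] ** (-1.0 / 3.0)
        d, _, _ = enumerate_geodesics(sub)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    acc += (W[i, V[a]] * W[i, V[b]]) ** (1.0 / 3.0) / d[a, b]
        out[i] = acc / (k * (k - 1))
    return out


def onnela_clustering(W):
    G = nx.from_numpy_array(W)
    c = nx.clustering(G, weight="weight")
    return np.array([c[i] for i in range(len(W))])


def eigvec_centrality_dense(W):
    vals, vecs = np.linalg.eigh(W)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max() if v.max() > 0 else v


def pagerank_dense(W, damping=0.85):
    n = len(W)
    s = W.sum(axis=1)
    dangling = (s == 0).astype(float)
    T = np.zeros((n, n))
    for i in range(n):
        if s[i] > 0:
            T[i] = W[i] / s[i]
    M = T.T + np.outer(np.ones(n), dangling) / n
    r = np.linalg.solve(np.eye(n) - damping * M, (1.0 - damping) / n * np.ones(n))
    return r / r.sum()


def nodal_path_and_eccentricity(dist):
    n = len(dist)
    cpl, ecc = np.zeros(n), np.zeros(n)
    for i in range(n):
        finite = [dist[i, j] for j in range(n) if j != i and math.isfinite(dist[i, j])]
        if finite:
            cpl[i] = sum(finite) / len(finite)
            ecc[i] = max(finite)
    return cpl, ecc


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------

def global_metrics_brute(W, dist):
    n = len(W)
    n_edges = sum(1 for i in range(n) for j in range(i + 1, n) if W[i, j] > 0)
    density = n_edges / (n * (n - 1) / 2)
    eff = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(dist[i, j]) and dist[i, j] > 0:
                eff += 1.0 / dist[i, j]
    eff /= n * (n - 1)
    num = den = 0.0
    deg = (W > 0).sum(axis=1)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3:
                    num += (W[i, j] * W[j, k] * W[k, i]) ** (1.0 / 3.0)
        den += deg[i] * (deg[i] - 1)
    transitivity = num / den if den > 0 else 0.0
    G = nx.from_numpy_array((W > 0).astype(int))
    try:
        assort = nx.degree_assortativity_coefficient(G)
    except (ZeroDivisionError, ValueError):
        assort = np.nan
    return density, eff, transitivity, assort


# ---------------------------------------------------------------------------
# EBM likelihood by direct stage-sum enumeration
# ---------------------------------------------------------------------------

def ebm_loglik_stage_sum(log_p_event, log_p_noevent, order) -> float:
    """Direct evaluation of the uniform-stage event-based model likelihood."""
    S, N = log_p_event.shape
    total = 0.0
    for s in range(S):
        acc = 0.0
        for k in range(N + 1):
            term = sum(log_p_event[s, order[i]] for i in range(k))
            term += sum(log_p_noevent[s, order[i]] for i in range(k, N))
            acc += math.exp(term)
        total += math.log(acc / (N + 1))
    return total


# ---------------------------------------------------------------------------
# full-metric comparison used by the oracle-equivalence checks
# ---------------------------------------------------------------------------

def max_metric_deviation(W, seed=0) -> float:
    """Largest absolute disagreement between connebm's 12 nodal + 4 global
    metrics and the independent reference implementations on one graph."""
    from connebm import WeightedConnectome, community_partition
    from connebm.connectome import weights_to_lengths
    from connebm.graph_metrics import global_metrics, node_metric_table

    c = WeightedConnectome([f"n{i}" for i in range(len(W))], W)
    part = community_partition(c, seed=seed)
    tbl = node_metric_table(c, partition=part)
    L = weights_to_lengths(c)
    dist, node_bc, edge_bc = enumerate_geodesics(L)
    deg, stren = degree_strength(W)
    cpl, ecc = nodal_path_and_eccentricity(dist)
    refs = {
        "degree": deg,
        "strength": stren,
        "degree_zscore": within_module_degree_z(W, part.assignment),
        "participation_coef": participation(W, part.assignment),
        "node_betweenness": node_bc,
        "edge_betweenness_nodal": edge_bc,
        "local_efficiency": local_efficiency_brute(W),
        "char_path_length": cpl,
        "eccentricity": ecc,
        "clustering_coef": onnela_clustering(W),
        "eigenvector_centrality": eigvec_centrality_dense(W),
        "pagerank_centrality": pagerank_dense(W),
    }
    dev = 0.0
    for name, ref in refs.items():
        dev = max(dev, float(np.max(np.abs(tbl[name].to_numpy() - ref))))
    gm = global_metrics(c)
    density, eff, trans, assort = global_metrics_brute(W, dist)
    dev = max(dev, abs(gm.density - density), abs(gm.global_efficiency - eff),
              abs(gm.transitivity - trans))
    if np.isnan(assort) or np.isnan(gm.assortativity):
        assert np.isnan(assort) and np.isnan(gm.assortativity)
    else:
        dev = max(dev, abs(gm.assortativity - assort))
    return dev


# ---------------------------------------------------------------------------
# random test graphs
# ---------------------------------------------------------------------------

def random_normalized_graph(rng, n_min=4, n_max=8):
    """Random symmetric weighted graph, max weight 1, zero diagonal, >= 1 edge."""
    n = int(rng.integers(n_min, n_max + 1))
    density = rng.uniform(0.3, 0.95)
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    if not present.any():
        present[rng.integers(len(present))] = True
    W[iu] = np.where(present, rng.uniform(0.05, 1.0, len(iu[0])), 0.0)
    W = W + W.T
    W /= W.max()
    return W
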