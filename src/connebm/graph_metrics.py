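"""Weighted graph-theory metrics for brain connectomes.

Twelve nodal metrics in three families — hubs (degree, strength, degree
z-score), importance (local efficiency, characteristic path length,
participation coefficient, node betweenness, nodal edge betweenness,
eigenvector centrality, PageRank centrality) and segregation/integration
(clustering coefficient, eccentricity) — plus four global metrics (density,
global efficiency, transitivity, assortativity). Conventions follow the
Brain Connectivity Toolbox for weighted undirected graphs: weights are
connection densities in [0, 1], path lengths use the inverse-weight
conversion, clustering and transitivity use cube-root weight products.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .connectome import WeightedConnectome, weights_to_lengths
from .errors import InvalidConnectomeError, NumericalError

__all__ = [
    "ModulePartition",
    "GlobalMetricSet",
    "NODE_METRICS",
    "shortest_path_matrix",
    "node_degree",
    "node_strength",
    "community_partition",
    "modularity",
    "degree_zscore",
    "participation_coefficient",
    "betweenness",
    "eigenvector_centrality",
    "pagerank_centrality",
    "local_efficiency",
    "nodal_path_length",
    "eccentricity",
    "clustering_coefficient",
    "global_metrics",
    "node_metric_table",
]

#: Column order of the nodal biomarker set.
NODE_METRICS = [
    "degree",
    "strength",
    "degree_zscore",
    "local_efficiency",
    "char_path_length",
    "participation_coef",
    "node_betweenness",
    "edge_betweenness_nodal",
    "eigenvector_centrality",
    "pagerank_centrality",
    "clustering_coef",
    "eccentricity",
]

_TIE_TOL = 1e-12  # geodesic length-equality tolerance


@dataclass
class ModulePartition:
    """Node-to-module assignment with its Newman modularity."""

    assignment: np.ndarray  # module id per node
    modularity: float

    @property
    def n_modules(self) -> int:
        return int(len(np.unique(self.assignment)))


@dataclass
class GlobalMetricSet:
    density: float
    global_efficiency: float
    transitivity: float
    assortativity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "density": self.density,
            "global_efficiency": self.global_efficiency,
            "transitivity": self.transitivity,
            "assortativity": self.assortativity,
        }


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def shortest_path_matrix(L: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances on a length matrix.

    ``L`` holds edge lengths with +inf for unconnected pairs and 0 on the
    diagonal. Disconnected pairs stay +inf in the output.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    finite = np.isfinite(L) & (L > 0)
    graph = csr_matrix((L[finite], np.nonzero(finite)), shape=(n, n))
    D = _csgraph_dijkstra(graph, directed=False)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def node_degree(c: WeightedConnectome) -> np.ndarray:
    """Count of nonzero neighbors per node."""
    return (c.weights > 0).sum(axis=1).astype(float)


def node_strength(c: WeightedConnectome) -> np.ndarray:
    """Sum of connection weights per node."""
    return c.weights.sum(axis=1)


# ---------------------------------------------------------------------------
# community structure (Louvain)
# ---------------------------------------------------------------------------

def modularity(W: np.ndarray, assignment: np.ndarray) -> float:
    """Weighted Newman modularity of a partition of an undirected graph."""
    W = np.asarray(W, dtype=float)
    s = W.sum(axis=1)
    two_m = s.sum()
    if two_m == 0:
        return 0.0
    same = assignment[:, None] == assignment[None, :]
    return float(((W - np.outer(s, s) / two_m) * same).sum() / two_m)


def _louvain_local_move(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One level of Louvain local moving on a (possibly self-looped) matrix."""
    n = W.shape[0]
    strength = W.sum(axis=1)
    two_m = strength.sum()
    comm = np.arange(n)
    stot = strength.copy()
    if two_m == 0:
        return comm
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            nbrs = np.nonzero(W[i])[0]
            links: dict[int, float] = {}
            for j in nbrs:
                if j != i:
                    links[comm[j]] = links.get(comm[j], 0.0) + W[i, j]
            stot[ci] -= strength[i]
            base = links.get(ci, 0.0) - strength[i] * stot[ci] / two_m
            best_c, best_gain = ci, 0.0
            for cand in sorted(links):
                gain = links[cand] - strength[i] * stot[cand] / two_m - base
                if gain > best_gain + 1e-12:
                    best_c, best_gain = cand, gain
            stot[best_c] += strength[i]
            if best_c != ci:
                comm[i] = best_c
                improved = True
    return comm


def community_partition(c: WeightedConnectome, seed: int = 0) -> ModulePartition:
    """Modularity-maximizing partition by seeded Louvain agglomeration.

    Greedy local moves followed by graph aggregation, repeated until the
    modularity stops improving; the seed fixes the node visiting order and
    hence tie-breaking.
    """
    if c.n_nodes < 2:
        raise InvalidConnectomeError("community detection needs >= 2 nodes")
    rng = np.random.default_rng(seed)
    W = c.weights.astype(float).copy()
    assignment = np.arange(c.n_nodes)
    best_q = modularity(c.weights, assignment)
    while True:
        comm = _louvain_local_move(W, rng)
        # relabel communities compactly and propagate to original nodes
        _, comm = np.unique(comm, return_inverse=True)
        new_assignment = comm[assignment]
        q = modularity(c.weights, new_assignment)
        if q <= best_q + 1e-12:
            break
        best_q = q
        assignment = new_assignment
        # aggregate: community graph with self-loops holding internal weight
        k = comm.max() + 1
        P = np.zeros((W.shape[0], k))
        P[np.arange(W.shape[0]), comm] = 1.0
        W = P.T @ W @ P
        if k == 1:
            break
    # isolated-node communities keep their own label; relabel compactly
    _, assignment = np.unique(assignment, return_inverse=True)
    q = modularity(c.weights, assignment)
    single = np.zeros(c.n_nodes, dtype=int)
    if modularity(c.weights, single) >= q:
        assignment, q = single, modularity(c.weights, single)
    return ModulePartition(assignment=assignment, modularity=q)


def degree_zscore(
    c: WeightedConnectome,
    p: ModulePartition | None = None,
    *,
    within_module: bool = True,
) -> np.ndarray:
    """Within-module degree z-score (sample sd); z=0 for zero-spread modules.

    With ``within_module=False`` the z-score is taken over the whole network
    instead (no partition needed).
    """
    deg_all = node_degree(c)
    if not within_module:
        sd = deg_all.std(ddof=1) if len(deg_all) > 1 else 0.0
        return (deg_all - deg_all.mean()) / sd if sd > 0 else np.zeros_like(deg_all)
    if p is None:
        raise ValueError("within-module z-score requires a partition")
    A = c.weights > 0
    z = np.zeros(c.n_nodes)
    for m in np.unique(p.assignment):
        idx = np.nonzero(p.assignment == m)[0]
        k_in = A[np.ix_(idx, idx)].sum(axis=1).astype(float)
        if len(idx) > 1:
            sd = k_in.std(ddof=1)
            if sd > 0:
                z[idx] = (k_in - k_in.mean()) / sd
    return z


def participation_coefficient(
    c: WeightedConnectome, p: ModulePartition
) -> np.ndarray:
    """P_i = 1 - sum_m (s_im / s_i)^2; 0 for isolated nodes.

    0 when all of a node's strength stays inside its own module, approaching
    1 when strength is spread evenly across many modules.
    """
    s = node_strength(c)
    modules = np.unique(p.assignment)
    s_im = np.stack([c.weights[:, p.assignment == m].sum(axis=1) for m in modules])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s > 0, s_im / np.where(s > 0, s, 1.0), 0.0)
    P = 1.0 - (frac**2).sum(axis=0)
    P[s == 0] = 0.0
    return P


# ---------------------------------------------------------------------------
# betweenness (Brandes on weighted geodesics)
# ---------------------------------------------------------------------------

def betweenness(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Node betweenness and nodal edge betweenness on a length matrix.

    Brandes accumulation over weighted shortest paths; co-optimal geodesics
    (length equal within 1e-12) are counted fractionally. Each unordered
    source-target pair is counted once. The nodal edge-betweenness biomarker
    is the sum of edge betweenness over edges incident to the node.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    nbrs = [np.nonzero(np.isfinite(L[v]) & (np.arange(n) != v))[0] for v in range(n)]
    node_bc = np.zeros(n)
    edge_bc = np.zeros((n, n))
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(n)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for w in nbrs[v]:
                nd = d + L[v, w]
                if nd < dist[w] - _TIE_TOL:
                    dist[w] = nd
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (nd, w))
                elif abs(nd - dist[w]) <= _TIE_TOL and not done[w]:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                contrib = sigma[v] / sigma[w] * (1.0 + delta[w])
                edge_bc[v, w] += contrib
                delta[v] += contrib
            if w != s:
                node_bc[w] += delta[w]
    node_bc /= 2.0  # each unordered pair visited from both endpoints
    edge_full = (edge_bc + edge_bc.T) / 2.0
    return node_bc, edge_full.sum(axis=1)


# ---------------------------------------------------------------------------
# spectral centralities
# ---------------------------------------------------------------------------

def eigenvector_centrality(
    c: WeightedConnectome, *, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Leading eigenvector of W by power iteration, nonnegative, max-norm 1."""
    W = c.weights
    n = c.n_nodes
    wmax = W.max(initial=0.0)
    if wmax == 0:
        return np.zeros(n)
    # positive diagonal shift: same eigenvectors, but breaks the +/- lambda
    # oscillation of bipartite components
    shift = wmax
    v = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        nv = W @ v + shift * v
        norm = np.linalg.norm(nv)
        if norm == 0:
            raise NumericalError("power iteration collapsed to the zero vector")
        nv /= norm
        if np.max(np.abs(nv - v)) < tol:
            v = nv
            break
        v = nv
    else:
        raise NumericalError("eigenvector centrality did not converge")
    v = np.abs(v)
    return v / v.max()


def pagerank_centrality(
    c: WeightedConnectome,
    damping: float = 0.85,
    *,
    tol: float = 1e-13,
    max_iter: int = 10_000,
) -> np.ndarray:
    """PageRank with strength-weighted transitions; dangling nodes teleport uniformly.

    The stationary vector sums to 1. ``damping=0`` gives the uniform
    distribution regardless of structure.
    """
    W = c.weights
    n = c.n_nodes
    s = W.sum(axis=1)
    dangling = s == 0
    T = np.zeros((n, n))
    nz = ~dangling
    T[nz] = W[nz] / s[nz, None]
    r = np.ones(n) / n
    for _ in range(max_iter):
        nr = (1.0 - damping) / n + damping * (T.T @ r + r[dangling].sum() / n)
        if np.max(np.abs(nr - r)) < tol:
            r = nr
            break
        r = nr
    else:
        raise NumericalError("PageRank did not converge")
    return r / r.sum()


# ---------------------------------------------------------------------------
# efficiency, paths, clustering
# ---------------------------------------------------------------------------

def nodal_path_length(D: np.ndarray) -> np.ndarray:
    """Mean finite shortest-path distance to other nodes; 0 for isolated nodes."""
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        d = np.delete(D[i], i)
        finite = np.isfinite(d)
        if finite.any():
            out[i] = d[finite].mean()
    return out


def eccentricity(D: np.ndarray) -> np.ndarray:
    """Max finite shortest-path distance per node; 0 for isolated nodes."""
    n = D.shape[0]
    out = np.zeros(n)
    for i in range(n):
        d = np.delete(D[i], i)
        finite = np.isfinite(d)
        if finite.any():
            out[i] = d[finite].max()
    return out


def local_efficiency(c: WeightedConnectome) -> np.ndarray:
    """Weighted local efficiency with cube-root weight products (BCT convention).

    For node i with neighbors V: the efficiency of communication among V when
    routed around i, E_i = sum_{j != h in V} (w_ij w_ih)^{1/3} d_jh^{-1}
    / (k_i (k_i - 1)), where d_jh is the shortest path among the neighbors
    computed on cube-root lengths. Nodes with < 2 neighbors score 0.
    """
    W = c.weights
    n = c.n_nodes
    out = np.zeros(n)
    with np.errstate(divide="ignore"):
        L3 = np.where(W > 0, np.where(W > 0, W, 1.0) ** (-1.0 / 3.0), np.inf)
    np.fill_diagonal(L3, 0.0)
    for i in range(n):
        V = np.nonzero(W[i] > 0)[0]
        k = len(V)
        if k < 2:
            continue
        D = shortest_path_matrix(L3[np.ix_(V, V)])
        with np.errstate(divide="ignore"):
            invd = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
        invd[~np.isfinite(D)] = 0.0
        np.fill_diagonal(invd, 0.0)
        sw = W[i, V] ** (1.0 / 3.0)
        out[i] = float((np.outer(sw, sw) * invd).sum()) / (k * (k - 1))
    return out


def clustering_coefficient(c: WeightedConnectome) -> np.ndarray:
    """Onnela weighted clustering: cube-root triangle intensity over possible pairs."""
    W = c.weights
    cube = W ** (1.0 / 3.0)
    cyc3 = np.diag(cube @ cube @ cube)
    k = node_degree(c)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, cyc3 / np.where(denom > 0, denom, 1.0), 0.0)
    return C


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------

def global_metrics(c: WeightedConnectome) -> GlobalMetricSet:
    """Density, global efficiency, weighted transitivity, degree assortativity."""
    W = c.weights
    n = c.n_nodes
    if n < 3:
        raise InvalidConnectomeError("transitivity undefined for n < 3")
    iu = np.triu_indices(n, k=1)
    edges = W[iu] > 0
    density = float(edges.sum()) / (n * (n - 1) / 2)

    D = shortest_path_matrix(weights_to_lengths(c))
    with np.errstate(divide="ignore"):
        invD = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    invD[~np.isfinite(D)] = 0.0
    np.fill_diagonal(invD, 0.0)
    geff = float(invD.sum()) / (n * (n - 1))

    cube = W ** (1.0 / 3.0)
    cyc3 = np.diag(cube @ cube @ cube)
    k = node_degree(c)
    denom = (k * (k - 1)).sum()
    transitivity = float(cyc3.sum() / denom) if denom > 0 else 0.0

    deg = k
    src, dst = iu[0][edges], iu[1][edges]
    if len(src) == 0:
        assort = np.nan
    else:
        x = np.concatenate([deg[src], deg[dst]])
        y = np.concatenate([deg[dst], deg[src]])
        sx = x.std()
        if sx == 0:
            assort = np.nan
        else:
            assort = float(np.corrcoef(x, y)[0, 1])
    return GlobalMetricSet(density, geff, transitivity, assort)


# ---------------------------------------------------------------------------
# assembled nodal biomarker table
# ---------------------------------------------------------------------------

def node_metric_table(
    c: WeightedConnectome,
    seed: int = 0,
    *,
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """All 12 nodal metrics of one connectome as a region x metric frame."""
    part = partition if partition is not None else community_partition(c, seed=seed)
    L = weights_to_lengths(c)
    D = shortest_path_matrix(L)
    nbc, ebc = betweenness(L)
    cols = {
        "degree": node_degree(c),
        "strength": node_strength(c),
        "degree_zscore": degree_zscore(c, part),
        "local_efficiency": local_efficiency(c),
        "char_path_length": nodal_path_length(D),
        "participation_coef": participation_coefficient(c, part),
        "node_betweenness": nbc,
        "edge_betweenness_nodal": ebc,
        "eigenvector_centrality": eigenvector_centrality(c),
        "pagerank_centrality": pagerank_centrality(c),
        "clustering_coef": clustering_coefficient(c),
        "eccentricity": eccentricity(D),
    }
    return pd.DataFrame(cols, index=pd.Index(c.node_labels, name="region"))[NODE_METRICS]
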