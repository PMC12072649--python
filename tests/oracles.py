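"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's computation routes: path-based
metrics are obtained by explicitly enumerating every shortest path, and
modularity by direct evaluation of the quadratic form over all sign
vectors.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def brute_force_centralities(g: nx.Graph) -> dict:
    """All ten node metrics from first principles (explicit path enumeration)."""
    nodes = list(g.nodes())
    n = len(nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            if through:
                stress[v] += through
                betweenness[v] += through / len(paths)
    out = {}
    diam = max(max(d.values()) for d in dist.values())
    for v in nodes:
        k = g.degree(v)
        neigh = list(g.neighbors(v))
        e_i = sum(1 for a, b in itertools.combinations(neigh, 2) if g.has_edge(a, b))
        clustering = 2.0 * e_i / (k * (k - 1)) if k >= 2 else 0.0
        total_dist = sum(dist[v][u] for u in nodes if u != v)
        # topological coefficient: shared-neighbor redundancy
        shared = []
        for j in nodes:
            if j == v:
                continue
            common = len(set(neigh) & set(g.neighbors(j)))
            if common:
                shared.append(common + (1 if g.has_edge(v, j) else 0))
        topo = float(np.mean(shared)) / k if (k >= 2 and shared) else 0.0
        out[v] = {
            "degree": float(k),
            "betweenness": betweenness[v],
            "closeness": 1.0 / total_dist,
            "clustering": clustering,
            "neighborhood_connectivity": float(np.mean([g.degree(u) for u in neigh])) if neigh else 0.0,
            "radiality": sum(diam + 1 - dist[v][u] for u in nodes if u != v) / (n - 1),
            "eccentricity": float(max(dist[v].values())),
            "avg_shortest_path": total_dist / (n - 1),
            "stress": stress[v],
            "topological_coefficient": topo,
        }
    return out


def direct_modularity_matrix(g: nx.Graph) -> np.ndarray:
    """Element-wise B_ij = A_ij - k_i k_j / (2m)."""
    nodes = list(g.nodes())
    m = g.number_of_edges()
    b = np.zeros((len(nodes), len(nodes)))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            a = 1.0 if g.has_edge(u, v) else 0.0
            b[i, j] = a - g.degree(u) * g.degree(v) / (2.0 * m)
    return b


def enumerate_best_bisection(g: nx.Graph):
    """Exhaustive max over all 2^n sign vectors of Q = s^T B s / (4m)."""
    nodes = list(g.nodes())
    n = len(nodes)
    b = direct_modularity_matrix(g)
    m = g.number_of_edges()
    best_q, best_s = -np.inf, None
    for bits in range(2**n):
        s = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(n)])
        q = float(s @ b @ s) / (4.0 * m)
        if q > best_q:
            best_q, best_s = q, s
    return best_q, {v: int(si) for v, si in zip(nodes, best_s)}


def random_connected_graph(rng: np.random.Generator, n_max: int = 30) -> nx.Graph:
    """Random connected simple graph: a random spanning tree plus extra edges."""
    n = int(rng.integers(4, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = rng.permutation(n)
    for i in range(1, n):
        j = int(rng.integers(i))
        g.add_edge(nodes[order[i]], nodes[order[j]])
    extra = int(rng.integers(0, max(2, n)))
    for _ in range(extra):
        u, v = rng.choice(n, size=2, replace=False)
        g.add_edge(nodes[u], nodes[v])
    return g
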