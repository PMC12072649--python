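"""Ten topological node metrics and the Functional Centrality Index (FCI).

The FCI is a weighted mean of z-standardized centrality metrics. Metrics
for which *smaller* is more central — average shortest path length,
eccentricity, and stress — are sign-inverted after standardization so that
a larger FCI always reads "more central". Betweenness carries a larger
default weight because bottleneck nodes mediating inter-module
communication are the prime therapeutic-target candidates in a disease
interactome.

Distance-based metrics are undefined across components, so every entry
point that needs them requires a connected graph.

Conventions (all on undirected simple graphs):

* betweenness ``C_B(i) = sum_{s<t, s,t != i} sigma_st(i) / sigma_st``,
  unnormalized, unordered source-target pairs;
* closeness ``C_C(i) = 1 / sum_j d(i, j)`` (reciprocal total distance,
  not the (n-1)-rescaled variant);
* stress ``S_i = sum_{s<t} sigma_st(i)`` — raw shortest-path counts;
* radiality ``R_i = sum_{j != i} (diam(G) + 1 - d(i, j)) / (n - 1)``;
* topological coefficient ``T_i`` = mean of ``J(i, j) / k_i`` over nodes j
  sharing at least one neighbor with i, where ``J(i, j)`` counts shared
  neighbors plus 1 if i and j are adjacent; 0 for nodes with degree <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

METRICS = [
    "degree",
    "betweenness",
    "closeness",
    "clustering",
    "neighborhood_connectivity",
    "radiality",
    "eccentricity",
    "avg_shortest_path",
    "stress",
    "topological_coefficient",
]

#: metrics where smaller raw values mean more central (inverted after z-scoring)
DEFAULT_INVERTED = frozenset({"avg_shortest_path", "eccentricity", "stress"})

CentralityTable = pd.DataFrame
"""One row per node (index = node id), one column per metric in METRICS."""


@dataclass(frozen=True)
class FCIWeights:
    """Nonnegative per-metric weights plus the set of sign-inverted metrics."""

    weights: dict = field(
        default_factory=lambda: {m: (2.0 if m == "betweenness" else 1.0) for m in METRICS}
    )
    inverted: frozenset = DEFAULT_INVERTED

    def __post_init__(self):
        unknown = set(self.weights) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metric(s) in weights: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "inverted", frozenset(self.inverted))

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))


def _require_connected(g: nx.Graph, min_nodes: int = 3) -> None:
    if g.number_of_nodes() < min_nodes:
        raise ValueError(f"graph must have at least {min_nodes} nodes, got {g.number_of_nodes()}")
    if nx.number_of_selfloops(g):
        raise ValueError("graph must be simple (self-loops present)")
    if not nx.is_connected(g):
        comps = sorted((sorted(map(str, c)) for c in nx.connected_components(g)), key=len)
        preview = "; ".join("{" + ",".join(c[:5]) + ("…" if len(c) > 5 else "") + "}" for c in comps[:4])
        raise ValueError(
            f"graph is disconnected ({len(comps)} components: {preview}); "
            "distance-based metrics are undefined across components"
        )


def _shortest_path_counts(g: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and shortest-path counts via BFS layering."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[u] for u in g.neighbors(v)] for v in nodes]
    dist = np.full((n, n), -1, dtype=np.int64)
    sigma = np.zeros((n, n), dtype=np.float64)
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if dist[s, w] == -1:
                        dist[s, w] = d
                        nxt.append(w)
                    if dist[s, w] == d:
                        sigma[s, w] += sigma[s, v]
            frontier = nxt
    return dist, sigma


def _stress(dist: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """S_i = sum over unordered pairs s<t of sigma_st(i).

    A shortest s-t path passes through i iff d(s,i)+d(i,t) = d(s,t); the
    number of such paths is sigma_si * sigma_it.
    """
    n = dist.shape[0]
    out = np.zeros(n)
    for i in range(n):
        on_path = dist[:, i][:, None] + dist[i, :][None, :] == dist
        counts = sigma[:, i][:, None] * sigma[i, :][None, :]
        counts = np.where(on_path, counts, 0.0)
        counts[i, :] = 0.0
        counts[:, i] = 0.0
        np.fill_diagonal(counts, 0.0)
        out[i] = np.triu(counts, k=1).sum()
    return out


def _topological_coefficient(g: nx.Graph, nodes: list) -> np.ndarray:
    out = np.zeros(len(nodes))
    neigh = {v: set(g.neighbors(v)) for v in nodes}
    for idx, i in enumerate(nodes):
        k_i = len(neigh[i])
        if k_i <= 1:
            continue
        shared = []
        for j in nodes:
            if j == i:
                continue
            common = len(neigh[i] & neigh[j])
            if common == 0:
                continue
            shared.append(common + (1 if j in neigh[i] else 0))
        if shared:
            out[idx] = float(np.mean(shared)) / k_i
    return out


def compute_centralities(g: nx.Graph) -> CentralityTable:
    """Compute all ten metrics for every node of a connected graph.

    Returns a DataFrame indexed by node id with the columns of
    :data:`METRICS`. Raises ``ValueError`` on disconnected input or fewer
    than 3 nodes.
    """
    _require_connected(g, min_nodes=3)
    nodes = list(g.nodes())
    n = len(nodes)
    dist, sigma = _shortest_path_counts(g, nodes)
    dist_f = dist.astype(float)
    row_sum = dist_f.sum(axis=1)

    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    betweenness_d = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([betweenness_d[v] for v in nodes])
    closeness = 1.0 / row_sum
    clustering_d = nx.clustering(g)
    clustering = np.array([clustering_d[v] for v in nodes])
    nbr_conn_d = nx.average_neighbor_degree(g)
    neighborhood_connectivity = np.array([nbr_conn_d[v] for v in nodes])
    eccentricity = dist_f.max(axis=1)
    diameter = eccentricity.max()
    radiality = (diameter + 1.0 - dist_f).sum(axis=1) - (diameter + 1.0)
    radiality /= n - 1
    avg_shortest_path = row_sum / (n - 1)
    stress = _stress(dist, sigma)
    topo = _topological_coefficient(g, nodes)

    return pd.DataFrame(
        {
            "degree": degree,
            "betweenness": betweenness,
            "closeness": closeness,
            "clustering": clustering,
            "neighborhood_connectivity": neighborhood_connectivity,
            "radiality": radiality,
            "eccentricity": eccentricity,
            "avg_shortest_path": avg_shortest_path,
            "stress": stress,
            "topological_coefficient": topo,
        },
        index=pd.Index(nodes, name="node"),
    )


def standardize_metrics(table: CentralityTable, weights: FCIWeights | None = None) -> pd.DataFrame:
    """Per-metric z-scores (population moments), sign-inverting the metrics
    in ``weights.inverted`` so that larger z always means more central.

    Zero-variance columns map to all-zero z with a warning: a constant
    metric carries no ranking information.
    """
    if weights is None:
        weights = FCIWeights()
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 nodes")
    z = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std()
        if sd == 0.0:
            warnings.warn(f"metric {col!r} has zero variance; z set to 0", stacklevel=2)
            z[col] = 0.0
            continue
        zi = (x - mu) / sd
        if col in weights.inverted:
            zi = -zi
        z[col] = zi
    return z


def compute_fci(z: pd.DataFrame, weights: FCIWeights | None = None) -> pd.Series:
    """FCI_i = (1/W) * sum_m w_m * z_{m,i}, W = sum_m w_m (> 0 required)."""
    if weights is None:
        weights = FCIWeights()
    missing = [m for m in z.columns if m not in weights.weights]
    if missing:
        raise ValueError(f"weights missing for metric(s): {missing}")
    W = sum(weights.weights[m] for m in z.columns)
    if W == 0:
        raise ValueError("total weight W must be positive")
    w = np.array([weights.weights[m] for m in z.columns])
    fci = (z.to_numpy(dtype=float) @ w) / W
    return pd.Series(fci, index=z.index, name="fci")


def fci_from_graph(g: nx.Graph, weights: FCIWeights | None = None):
    """Convenience: centralities -> z-scores -> FCI in one call."""
    weights = weights or FCIWeights()
    table = compute_centralities(g)
    z = standardize_metrics(table, weights)
    return table, z, compute_fci(z, weights)


def correlate_fci(fci: pd.Series, table: CentralityTable) -> pd.DataFrame:
    """Pearson r and two-sided p-value of the FCI against each raw metric.

    Constant metrics are reported with NaN r/p (correlation undefined).
    """
    if len(table) < 3:
        raise ValueError("correlation needs at least 3 nodes")
    rows = []
    f = fci.loc[table.index].to_numpy(dtype=float)
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(f) == 0.0:
            rows.append((col, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(f, x)
        rows.append((col, float(r), float(p)))
    return pd.DataFrame(rows, columns=["metric", "pearson_r", "p_value"]).set_index("metric")
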