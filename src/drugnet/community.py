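"""Leading-eigenvector modularity clustering and per-cluster target selection.

The modularity matrix of an undirected simple graph with adjacency A,
degrees k and m edges is ``B_ij = A_ij - k_i k_j / (2m)``. A two-way split
encoded as a sign vector s has modularity ``Q = s^T B s / (4m)``; the
leading-eigenvector method takes s from the signs of the eigenvector with
the largest eigenvalue of B, then recurses on each side using the
generalized modularity matrix

    B^(g)_ij = B_ij - delta_ij * sum_{k in g} B_ik

restricted to the subset g, which keeps the modularity gain of nested
splits additive. Each spectral split is refined by the deterministic
Kernighan-Lin-style fine-tuning sweep that accompanies the spectral method
(single-vertex moves, best-prefix rollback). A subset is indivisible when
the leading eigenvalue is non-positive (within tolerance) or the proposed
split does not increase Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

_EIG_TOL = 1e-9
_GAIN_TOL = 1e-12
_DENSE_LIMIT = 500


@dataclass(frozen=True)
class Partition:
    """Node -> community label (0..K-1) with the partition's modularity Q."""

    labels: dict
    q: float

    @property
    def k(self) -> int:
        return len(set(self.labels.values())) if self.labels else 0

    def members(self, community: int) -> list:
        return [v for v, c in self.labels.items() if c == community]


def modularity_matrix(g: nx.Graph, node_subset=None) -> np.ndarray:
    """Dense B (or generalized B^(g) when a proper subset is given).

    Rows of the full-graph B sum to zero; the generalized matrix restores
    that property on subgraphs by absorbing each row's out-of-subset mass
    into the diagonal.
    """
    nodes = list(g.nodes())
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no modularity matrix")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("graph has no edges")
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)  # unweighted by contract
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / (2.0 * m)
    if node_subset is None:
        return b
    subset = list(node_subset)
    if not subset:
        raise ValueError("node subset must be nonempty")
    index = {v: i for i, v in enumerate(nodes)}
    idx = np.array([index[v] for v in subset])
    bg = b[np.ix_(idx, idx)]
    bg = bg - np.diag(bg.sum(axis=1))
    return bg


def modularity(g: nx.Graph, partition: Partition | dict) -> float:
    """Q of a partition: (1/2m) * sum over same-community pairs of B_ij."""
    labels = partition.labels if isinstance(partition, Partition) else partition
    missing = [v for v in g.nodes() if v not in labels]
    if missing:
        raise ValueError(f"partition is missing label(s) for: {missing[:5]}")
    m = g.number_of_edges()
    b = modularity_matrix(g)
    nodes = list(g.nodes())
    lab = np.array([labels[v] for v in nodes])
    same = lab[:, None] == lab[None, :]
    return float((b * same).sum() / (2.0 * m))


def _leading_eigenpair(b: np.ndarray) -> tuple[float, np.ndarray]:
    n = b.shape[0]
    if n <= _DENSE_LIMIT:
        vals, vecs = np.linalg.eigh(b)
        return float(vals[-1]), vecs[:, -1]
    v0 = np.ones(n) / np.sqrt(n)  # deterministic start for reproducibility
    try:
        vals, vecs = spla.eigsh(b, k=1, which="LA", v0=v0, tol=_EIG_TOL)
    except spla.ArpackNoConvergence as exc:  # pragma: no cover
        raise RuntimeError(f"eigen-solver failed to converge on n={n} subset") from exc
    return float(vals[0]), vecs[:, 0]


def _fine_tune(bg: np.ndarray, s: np.ndarray, max_sweeps: int = 30) -> np.ndarray:
    """Kernighan-Lin-style refinement of a sign vector.

    Repeatedly sweeps over all vertices, moving each exactly once (the move
    with the largest change in s^T B s, even if negative), then rolls back
    to the best prefix of the sweep; stops when a sweep yields no gain.
    Deterministic; the standard fine-tuning stage of the spectral method.
    """
    n = len(s)
    for _ in range(max_sweeps):
        s_sweep = s.copy()
        bs = bg @ s_sweep
        obj = float(s_sweep @ bs)
        best_obj, best_prefix = obj, 0
        moved = np.zeros(n, dtype=bool)
        flips: list[int] = []
        for step in range(n):
            gains = -4.0 * s_sweep * bs + 4.0 * np.diag(bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            obj += gains[i]
            bs = bs - 2.0 * s_sweep[i] * bg[:, i]
            s_sweep[i] = -s_sweep[i]
            moved[i] = True
            flips.append(i)
            if obj > best_obj + 1e-12:
                best_obj, best_prefix = obj, step + 1
        if best_prefix == 0:
            return s
        s = s.copy()
        for i in flips[:best_prefix]:
            s[i] = -s[i]
    return s


def leading_eigenvector_bisect(g: nx.Graph, node_subset=None):
    """Propose a two-way split of ``node_subset`` (default: all nodes).

    Returns ``(signs, delta_q)`` where ``signs`` maps node -> +1/-1
    (eigenvector components >= 0 go to +1), or ``None`` when the subset is
    indivisible (leading eigenvalue <= tolerance, all-one-sign vector, or
    no positive modularity gain).
    """
    subset = list(node_subset) if node_subset is not None else list(g.nodes())
    if len(subset) < 2:
        raise ValueError("bisection needs a subset of at least 2 nodes")
    bg = modularity_matrix(g, subset if node_subset is not None else None)
    lam, v = _leading_eigenpair(bg)
    if lam <= _EIG_TOL:
        return None
    s = np.where(v >= 0, 1.0, -1.0)
    s = _fine_tune(bg, s)
    if np.all(s == s[0]):
        return None
    m = g.number_of_edges()
    delta_q = float(s @ bg @ s) / (4.0 * m)
    if delta_q <= _GAIN_TOL:
        return None
    return {node: int(si) for node, si in zip(subset, s)}, delta_q


def detect_communities(g: nx.Graph, max_k: int | None = None, seed: int | None = None) -> Partition:
    """Recursive leading-eigenvector clustering of a connected graph.

    Splitting stops when no subset yields a positive modularity gain or
    ``max_k`` communities are reached. Labels are 0..K-1 in order of
    decreasing community size (ties by smallest member id). ``seed`` is
    accepted for interface symmetry; the procedure is deterministic.
    """
    del seed
    if max_k is not None and max_k < 1:
        raise ValueError("max_k must be >= 1")
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError("detect_communities requires a connected graph")
    communities = [list(g.nodes())]
    # queue of splittable groups; each pass splits the first divisible one
    frontier = [0]
    while frontier:
        if max_k is not None and len(communities) >= max_k:
            break
        gi = frontier.pop(0)
        group = communities[gi]
        if len(group) < 2:
            continue
        result = leading_eigenvector_bisect(g, group)
        if result is None:
            continue
        signs, _ = result
        left = [v for v in group if signs[v] > 0]
        right = [v for v in group if signs[v] < 0]
        communities[gi] = left
        communities.append(right)
        frontier.extend([gi, len(communities) - 1])
    order = sorted(range(len(communities)), key=lambda i: (-len(communities[i]), str(min(map(str, communities[i])))))
    labels = {}
    for new_label, old in enumerate(order):
        for v in communities[old]:
            labels[v] = new_label
    return Partition(labels=labels, q=modularity(g, labels))


def apply_overrides(partition: Partition, g: nx.Graph, overrides: dict) -> Partition:
    """Force specific nodes into specific communities (manual curation)."""
    labels = dict(partition.labels)
    for node, cluster in overrides.items():
        if node not in labels:
            raise ValueError(f"override for unknown node {node!r}")
        labels[node] = int(cluster)
    return Partition(labels=labels, q=modularity(g, labels))


def select_targets(fci: pd.Series, partition: Partition, n_targets: int = 5) -> dict:
    """Top-``n_targets`` genes by FCI per community (descending FCI, ties
    broken lexicographically by gene id).

    Communities smaller than ``n_targets`` return all members with a
    warning. Returns {community label: [gene, ...]}.
    """
    fci_nodes = set(fci.index)
    part_nodes = set(partition.labels)
    if fci_nodes != part_nodes:
        raise ValueError("fci and partition must cover the same node set")
    out = {}
    for c in sorted(set(partition.labels.values())):
        members = partition.members(c)
        if len(members) < n_targets:
            warnings.warn(
                f"community {c} has only {len(members)} gene(s) (< n_targets={n_targets})",
                stacklevel=2,
            )
        ranked = sorted(members, key=lambda v: (-fci.loc[v], str(v)))
        out[c] = ranked[:n_targets]
    return out
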