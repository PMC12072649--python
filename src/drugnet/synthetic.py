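"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator plants every signal the framework is supposed to recover:

* **Network** — a planted-partition (stochastic block model) gene graph
  with K communities (within/between edge probabilities p_in/p_out),
  restricted to its largest connected component;
* **Drugs** — each drug carries a latent pharmacology vector pointing at
  exactly one community centroid with a continuously varying strength
  (plus small isotropic noise); fingerprint bits are Bernoulli with
  probabilities driven by the latent and descriptors are a noisy linear
  read-out of it, so observable features are informative of pharmacology
  the way real fingerprints/descriptors are. At least one planted
  polypharmacology drug points strongly at two centroids at once and is
  the only drug with genuine multi-community affinity;
* **Interactions** — labels drawn Bernoulli with
  ``P = sigmoid(alpha * <drug latent, gene latent> + beta)`` where beta is
  calibrated so the positive rate matches the configured 10%; gene
  disease labels mark membership of a designated disease community.

Real SMILES are unnecessary here: features are emitted directly at the
configured widths (structure parsing is exercised separately on genuine
small molecules).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from drugnet.community import Partition


@dataclass
class SyntheticConfig:
    n_genes: int = 100
    k_clusters: int = 5
    p_in: float = 0.3
    p_out: float = 0.02
    n_drugs: int = 200
    latent_dim: int = 8
    positive_rate: float = 0.10
    noise_sd: float = 0.1        # isotropic latent noise (off-axis affinity)
    feature_noise_sd: float = 0.3  # descriptor read-out noise
    gene_noise_sd: float = 0.05
    alpha: float = 8.0           # signal strength: the single task-difficulty knob
    gamma_max: float = 0.8       # max single-community alignment strength
    n_planted: int = 1
    n_fp_bits: int = 128
    n_desc: int = 32
    n_pairs: int = 5000
    disease_cluster: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must be in (0, 1)")
        if self.n_genes < 3 * self.k_clusters:
            raise ValueError("n_genes must be at least 3 per cluster")
        if self.latent_dim < max(1, self.k_clusters):
            raise ValueError("latent_dim must be >= k_clusters (orthogonal centroids)")

    def to_dict(self):
        return asdict(self)


@dataclass
class DrugSet:
    ids: list
    latents: np.ndarray          # (n_drugs, latent_dim)
    fingerprints: np.ndarray     # (n_drugs, n_fp_bits) uint8
    descriptors: np.ndarray      # (n_drugs, n_desc) float
    aligned_cluster: dict        # drug_id -> its single aligned community
    alignment_strength: dict     # drug_id -> gamma in [0, gamma_max]
    planted_ids: list = field(default_factory=list)
    planted_clusters: dict = field(default_factory=dict)  # planted id -> (c1, c2)


def cluster_centroids(cfg: SyntheticConfig) -> np.ndarray:
    """K orthonormal unit directions in latent space, fixed by cfg.seed."""
    rng = np.random.default_rng(cfg.seed ^ 0x5EED)
    mat = rng.standard_normal((cfg.latent_dim, cfg.k_clusters))
    q, _ = np.linalg.qr(mat)
    return q.T  # (K, latent_dim)


def generate_network(cfg: SyntheticConfig, seed: int | None = None):
    """Planted-partition graph; returns (graph, true Partition).

    The largest connected component is retained; regeneration is attempted
    up to 10 times if it loses more than 10% of nodes or an entire
    community.
    """
    base = cfg.seed if seed is None else seed
    sizes = [cfg.n_genes // cfg.k_clusters] * cfg.k_clusters
    for i in range(cfg.n_genes - sum(sizes)):
        sizes[i] += 1
    for attempt in range(10):
        rng_seed = int(np.random.default_rng(base + 104729 * attempt).integers(2**31 - 1))
        p = np.full((cfg.k_clusters, cfg.k_clusters), cfg.p_out)
        np.fill_diagonal(p, cfg.p_in)
        sbm = nx.stochastic_block_model(sizes, p, seed=rng_seed)
        labels = {}
        mapping = {}
        for node, data in sbm.nodes(data=True):
            name = f"G{node:04d}"
            mapping[node] = name
            labels[name] = int(data["block"])
        g = nx.relabel_nodes(nx.Graph(sbm.edges()), mapping)
        g.add_nodes_from(mapping.values())
        if g.number_of_edges() == 0:
            continue
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
        labels = {v: labels[v] for v in g.nodes()}
        big_enough = g.number_of_nodes() >= 0.9 * cfg.n_genes
        all_clusters = len(set(labels.values())) == cfg.k_clusters
        if big_enough and all_clusters and nx.is_connected(g):
            from drugnet.community import modularity

            return g, Partition(labels=labels, q=modularity(g, labels))
    raise RuntimeError("failed to generate a usable connected planted-partition graph in 10 attempts")


def gene_latents(partition: Partition, cfg: SyntheticConfig, seed: int | None = None) -> dict:
    """Per-gene latent = own-community centroid + small isotropic noise."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 17)
    centroids = cluster_centroids(cfg)
    return {
        v: centroids[c] + cfg.gene_noise_sd * rng.standard_normal(cfg.latent_dim)
        for v, c in sorted(partition.labels.items())
    }


def generate_drugs(cfg: SyntheticConfig, seed: int | None = None) -> DrugSet:
    """Drug latents plus feature read-outs (fingerprint bits, descriptors)."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 29)
    centroids = cluster_centroids(cfg)
    n = cfg.n_drugs
    ids = [f"D{i:04d}" for i in range(n)]
    clusters = rng.integers(cfg.k_clusters, size=n)
    gamma = rng.uniform(0.0, cfg.gamma_max, size=n)
    latents = gamma[:, None] * centroids[clusters] + cfg.noise_sd * rng.standard_normal((n, cfg.latent_dim))
    aligned_cluster = {ids[i]: int(clusters[i]) for i in range(n)}
    alignment_strength = {ids[i]: float(gamma[i]) for i in range(n)}
    planted_ids, planted_clusters = [], {}
    for i in rng.choice(n, size=cfg.n_planted, replace=False):
        c1, c2 = rng.choice(cfg.k_clusters, size=2, replace=False)
        latents[i] = centroids[c1] + centroids[c2] + 0.5 * cfg.noise_sd * rng.standard_normal(cfg.latent_dim)
        planted_ids.append(ids[i])
        planted_clusters[ids[i]] = (int(c1), int(c2))
        aligned_cluster.pop(ids[i])
        alignment_strength.pop(ids[i])
    # fingerprint bits: Bernoulli(sigmoid(W u + b)), sparse-ish via negative offset
    w = rng.standard_normal((cfg.n_fp_bits, cfg.latent_dim)) * (2.0 / np.sqrt(cfg.latent_dim))
    b = -1.0
    probs = 1.0 / (1.0 + np.exp(-(latents @ w.T + b)))
    fingerprints = (rng.random(probs.shape) < probs).astype(np.uint8)
    # descriptors: linear map of latents + Gaussian noise
    m = rng.standard_normal((cfg.n_desc, cfg.latent_dim))
    descriptors = latents @ m.T + cfg.feature_noise_sd * rng.standard_normal((n, cfg.n_desc))
    return DrugSet(ids=ids, latents=latents, fingerprints=fingerprints,
                   descriptors=descriptors, aligned_cluster=aligned_cluster,
                   alignment_strength=alignment_strength,
                   planted_ids=planted_ids, planted_clusters=planted_clusters)


def _calibrate_beta(logits: np.ndarray, target: float) -> float:
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = float(np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))))
        if rate < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_interactions(drugs: DrugSet, latents_by_gene: dict, partition: Partition,
                          cfg: SyntheticConfig, seed: int | None = None):
    """Sample labeled (drug, gene) pairs from the planted interaction rule.

    Returns ``(interaction DataFrame with true_prob column, gene disease
    labels dict)``. The intercept beta is calibrated by bisection so the
    expected positive rate over the sampled pairs matches the config; an
    error is raised if the achieved rate misses by more than 20%.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 43)
    genes = sorted(latents_by_gene)
    n_cells = len(drugs.ids) * len(genes)
    n_pairs = min(cfg.n_pairs, n_cells)
    flat = rng.choice(n_cells, size=n_pairs, replace=False)
    di, gi = np.divmod(flat, len(genes))
    gene_mat = np.array([latents_by_gene[g] for g in genes])
    raw = cfg.alpha * np.einsum("ij,ij->i", drugs.latents[di], gene_mat[gi])
    beta = _calibrate_beta(raw, cfg.positive_rate)
    probs = 1.0 / (1.0 + np.exp(-(raw + beta)))
    achieved = float(probs.mean())
    if abs(achieved - cfg.positive_rate) > 0.2 * cfg.positive_rate:
        raise RuntimeError(
            f"positive-rate calibration failed: got {achieved:.3f}, want {cfg.positive_rate}")
    labels = (rng.random(n_pairs) < probs).astype(int)
    table = pd.DataFrame({
        "drug_id": [drugs.ids[i] for i in di],
        "gene_id": [genes[i] for i in gi],
        "label": labels,
        "true_prob": probs,
    })
    gene_labels = {v: int(c == cfg.disease_cluster) for v, c in partition.labels.items()}
    return table, gene_labels


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    graph: nx.Graph
    partition: Partition          # planted ground truth
    drugs: DrugSet
    interactions: pd.DataFrame    # drug_id, gene_id, label, true_prob
    gene_labels: dict


def generate_study(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticStudy:
    """All fixtures in one call, mutually consistent, fixed by one seed."""
    seed = cfg.seed if seed is None else seed
    graph, partition = generate_network(cfg, seed)
    drugs = generate_drugs(cfg, seed)
    latents = gene_latents(partition, cfg, seed)
    interactions, gene_labels = generate_interactions(drugs, latents, partition, cfg, seed)
    return SyntheticStudy(config=cfg, graph=graph, partition=partition, drugs=drugs,
                          interactions=interactions, gene_labels=gene_labels)
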