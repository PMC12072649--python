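"""Multi-modal drug-gene interaction network with dual uncertainty.

Architecture, end to end:

* **Molecular encoder** — the binary fingerprint and the standardized
  descriptor vector each pass a two-layer perceptron (leaky-rectifier
  slope 0.2, dropout, layer norm); the two pathway outputs are
  concatenated and projected to the drug embedding width ``d_m``.
* **Cluster-aware gene encoder** — a learnable embedding per gene
  (Xavier-uniform) refined by two graph-attention layers (per-edge softmax
  attention over the neighborhood, multi-head with concatenation
  aggregation) and one global transformer-attention layer over the whole
  gene set; the community one-hot is concatenated and projected back to
  ``d_g`` (e.g. 517 -> 512 at defaults with K=5).
* **Dual cross-attention fusion** — drug-as-query and gene-as-query
  scaled dot-product attention between the two embeddings viewed as
  ``heads`` tokens of width ``d_k`` (scale 1/sqrt(d_k) = 1/8 at d_k=64),
  attention dropout 0.1; attended vectors are concatenated into a fused
  pair vector of width ``2*d_g``.
* **Heads** — interaction score ``s = sigmoid(Omega(fused))`` and
  aleatoric uncertainty ``u = 0.5 * sigmoid(Gamma(fused))`` (a softplus
  variant is available); a disease-gene head ``Theta`` on gene embeddings
  and fingerprint/descriptor decoders for the autoencoding objective.
* **MC dropout** — epistemic uncertainty is the variance of T stochastic
  forward passes with dropout kept active.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from drugnet.community import Partition
from drugnet.nn import Dropout, LayerNorm, Linear, Module, Parameter, Tensor, concat, no_grad
from drugnet.nn.layers import xavier_uniform


@dataclass
class ModelConfig:
    n_fp: int = 2048
    n_desc: int = 200
    d_m: int = 512  # drug embedding width
    d_g: int = 512  # gene embedding width
    n_gat_layers: int = 2
    gat_heads: int = 8
    transformer_heads: int = 8
    cross_heads: int = 8
    cross_head_dim: int = 64
    dropout_p: float = 0.2
    attention_dropout: float = 0.1
    k_clusters: int = 5
    gene_head_hidden: int = 256
    leaky_slope: float = 0.2
    uncertainty_scale: float = 0.5
    mc_passes: int = 10
    aleatoric_activation: str = "sigmoid"  # or "softplus"
    seed: int = 0

    def __post_init__(self):
        if self.cross_heads * self.cross_head_dim != self.d_g:
            raise ValueError("cross_heads * cross_head_dim must equal d_g")
        if self.d_m != self.d_g:
            raise ValueError("d_m must equal d_g (shared cross-attention width)")
        if self.d_g % self.gat_heads or self.d_g % self.transformer_heads:
            raise ValueError("d_g must be divisible by the head counts")
        if self.aleatoric_activation not in ("sigmoid", "softplus"):
            raise ValueError("aleatoric_activation must be 'sigmoid' or 'softplus'")

    @property
    def attention_scale(self) -> float:
        return 1.0 / np.sqrt(self.cross_head_dim)

    def to_dict(self) -> dict:
        return asdict(self)


def _leaky(x: Tensor, slope: float) -> Tensor:
    return x.leaky_relu(slope)


class _PathwayMLP(Module):
    """Two dense layers + leaky ReLU + dropout + layer norm (one encoder path)."""

    def __init__(self, rng, n_in, width, dropout_p, slope):
        super().__init__()
        self.fc1 = Linear(rng, n_in, width)
        self.fc2 = Linear(rng, width, width)
        self.norm = LayerNorm(width)
        self.drop = Dropout(dropout_p)
        self.slope = slope

    def __call__(self, x, rng, force_dropout=False):
        h = _leaky(self.fc1(x), self.slope)
        h = _leaky(self.fc2(h), self.slope)
        h = self.drop(h, rng, force=force_dropout)
        return self.norm(h)


class MolecularEncoder(Module):
    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.fp_path = _PathwayMLP(rng, cfg.n_fp, cfg.d_m, cfg.dropout_p, cfg.leaky_slope)
        self.desc_path = _PathwayMLP(rng, cfg.n_desc, cfg.d_m, cfg.dropout_p, cfg.leaky_slope)
        self.proj = Linear(rng, 2 * cfg.d_m, cfg.d_m)

    def __call__(self, fp: Tensor, desc: Tensor, rng, force_dropout=False) -> Tensor:
        a = self.fp_path(fp, rng, force_dropout)
        b = self.desc_path(desc, rng, force_dropout)
        return self.proj(concat([a, b], axis=-1))


class GATLayer(Module):
    """Dense multi-head graph attention with concatenation aggregation.

    Per head k: e_ij = LeakyReLU(a_k . [W_k h_i || W_k h_j]), softmax over
    the in-neighborhood of each target node, messages are W_k h_i.
    """

    def __init__(self, rng, d_in, d_out, heads, slope, attn_dropout):
        super().__init__()
        if d_out % heads:
            raise ValueError("d_out must be divisible by heads")
        self.heads = heads
        self.d_head = d_out // heads
        self.w = Linear(rng, d_in, d_out, bias=False)
        self.att_src = Parameter(xavier_uniform(rng, self.d_head, 1, shape=(heads, self.d_head)))
        self.att_dst = Parameter(xavier_uniform(rng, self.d_head, 1, shape=(heads, self.d_head)))
        self.slope = slope
        self.drop = Dropout(attn_dropout)

    def __call__(self, h: Tensor, adj_mask: np.ndarray, rng, force_dropout=False):
        """h: (M, d_in); adj_mask: (M, M) bool, adj_mask[j, i] True iff i in N(j)."""
        m = h.shape[0]
        hw = self.w(h).reshape(m, self.heads, self.d_head)          # (M, H, dh)
        src = (hw * self.att_src).sum(axis=-1)                      # (M, H): a_src . Wh_i
        dst = (hw * self.att_dst).sum(axis=-1)                      # (M, H): a_dst . Wh_j
        # logits[h, j, i] = LeakyReLU(src_i + dst_j), masked to the neighborhood
        logits = (src.transpose(1, 0).reshape(self.heads, 1, m)
                  + dst.transpose(1, 0).reshape(self.heads, m, 1)).leaky_relu(self.slope)
        neg = Tensor(np.where(adj_mask[None, :, :], 0.0, -1e30))
        alpha = (logits + neg).softmax(axis=-1)                     # rows over sources
        alpha_d = self.drop(alpha, rng, force=force_dropout)
        msgs = hw.transpose(1, 0, 2)                                # (H, M, dh)
        out = alpha_d @ msgs                                        # (H, M, dh)
        out = out.transpose(1, 0, 2).reshape(m, self.heads * self.d_head)
        return out, alpha.numpy()


class GlobalTransformerLayer(Module):
    """Multi-head self-attention over the full gene set (global context)."""

    def __init__(self, rng, d, heads, attn_dropout):
        super().__init__()
        self.heads = heads
        self.d_head = d // heads
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.drop = Dropout(attn_dropout)

    def __call__(self, h: Tensor, rng, force_dropout=False):
        m = h.shape[0]
        shape = (m, self.heads, self.d_head)
        q = self.wq(h).reshape(*shape).transpose(1, 0, 2)  # (H, M, dh)
        k = self.wk(h).reshape(*shape).transpose(1, 0, 2)
        v = self.wv(h).reshape(*shape).transpose(1, 0, 2)
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_head))
        alpha = logits.softmax(axis=-1)
        alpha_d = self.drop(alpha, rng, force=force_dropout)
        out = (alpha_d @ v).transpose(1, 0, 2).reshape(m, self.heads * self.d_head)
        return out, alpha.numpy()


class GeneEncoder(Module):
    """Learnable gene embeddings refined by GAT layers, a global
    transformer layer, and the cluster one-hot projection."""

    def __init__(self, rng, cfg: ModelConfig, gene_ids: list):
        super().__init__()
        self.gene_ids = sorted(map(str, gene_ids))
        self.index = {g: i for i, g in enumerate(self.gene_ids)}
        m = len(self.gene_ids)
        self.embedding = Parameter(xavier_uniform(rng, m, cfg.d_g))
        self.gat_layers = [
            GATLayer(rng, cfg.d_g, cfg.d_g, cfg.gat_heads, cfg.leaky_slope, cfg.attention_dropout)
            for _ in range(cfg.n_gat_layers)
        ]
        # width-restoring map after the concatenating final GAT layer
        self.gat_out = Linear(rng, cfg.d_g, cfg.d_g)
        self.transformer = GlobalTransformerLayer(rng, cfg.d_g, cfg.transformer_heads, cfg.attention_dropout)
        self.cluster_proj = Linear(rng, cfg.d_g + cfg.k_clusters, cfg.d_g)
        self.norm = LayerNorm(cfg.d_g)
        self.drop = Dropout(cfg.dropout_p)
        self.cfg = cfg

    def __call__(self, nodes: list, adj_mask: np.ndarray, cluster_onehot: np.ndarray,
                 rng, force_dropout=False):
        rows = np.array([self.index[str(v)] for v in nodes])
        h = self.embedding.take_rows(rows)
        attn = []
        for layer in self.gat_layers:
            h, a = layer(h, adj_mask, rng, force_dropout)
            h = _leaky(h, self.cfg.leaky_slope)
            attn.append(a)
        h = self.gat_out(h)
        g, a_t = self.transformer(h, rng, force_dropout)
        attn.append(a_t)
        z = self.cluster_proj(concat([g, Tensor(cluster_onehot)], axis=-1))
        z = self.drop(self.norm(z), rng, force=force_dropout)
        return z, attn


class CrossAttention(Module):
    """Dual scaled dot-product attention between drug and gene embeddings,
    each viewed as ``heads`` tokens of width ``d_k``."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        d = cfg.d_g
        self.heads, self.d_k = cfg.cross_heads, cfg.cross_head_dim
        self.scale = cfg.attention_scale
        self.wq_drug = Linear(rng, d, d)
        self.wk_gene = Linear(rng, d, d)
        self.wv_gene = Linear(rng, d, d)
        self.wq_gene = Linear(rng, d, d)
        self.wk_drug = Linear(rng, d, d)
        self.wv_drug = Linear(rng, d, d)
        self.drop = Dropout(cfg.attention_dropout)

    def _tokens(self, linear, x: Tensor):
        b = x.shape[0]
        return linear(x).reshape(b, self.heads, self.d_k)

    def __call__(self, drug_emb: Tensor, gene_emb: Tensor, rng, force_dropout=False):
        if drug_emb.shape[-1] != gene_emb.shape[-1]:
            raise ValueError("drug and gene embedding widths must match")
        b = drug_emb.shape[0]
        q_d = self._tokens(self.wq_drug, drug_emb)
        k_g = self._tokens(self.wk_gene, gene_emb)
        v_g = self._tokens(self.wv_gene, gene_emb)
        q_g = self._tokens(self.wq_gene, gene_emb)
        k_d = self._tokens(self.wk_drug, drug_emb)
        v_d = self._tokens(self.wv_drug, drug_emb)
        a_dg = ((q_d @ k_g.transpose(0, 2, 1)) * self.scale).softmax(axis=-1)  # (B, H, H)
        a_gd = ((q_g @ k_d.transpose(0, 2, 1)) * self.scale).softmax(axis=-1)
        h_dg = (self.drop(a_dg, rng, force=force_dropout) @ v_g).reshape(b, self.heads * self.d_k)
        h_gd = (self.drop(a_gd, rng, force=force_dropout) @ v_d).reshape(b, self.heads * self.d_k)
        fused = concat([h_dg, h_gd], axis=-1)
        return fused, a_dg.numpy(), a_gd.numpy()


class _ScorerMLP(Module):
    """Three dense layers (2d -> d -> d/2 -> 1) with leaky ReLU, layer norm,
    dropout — 1024 -> 512 -> 256 -> 1 at default widths."""

    def __init__(self, rng, d, dropout_p, slope):
        super().__init__()
        self.fc1 = Linear(rng, 2 * d, d)
        self.n1 = LayerNorm(d)
        self.fc2 = Linear(rng, d, d // 2)
        self.n2 = LayerNorm(d // 2)
        self.fc3 = Linear(rng, d // 2, 1)
        self.drop = Dropout(dropout_p)
        self.slope = slope

    def __call__(self, x, rng, force_dropout=False):
        h = self.drop(self.n1(_leaky(self.fc1(x), self.slope)), rng, force=force_dropout)
        h = self.drop(self.n2(_leaky(self.fc2(h), self.slope)), rng, force=force_dropout)
        return self.fc3(h)


class DTIModel(Module):
    """End-to-end drug-gene interaction model over a fixed gene graph.

    The graph (edge set) and community assignment are bound at
    construction; gene embeddings are keyed by gene id, so node order at
    call time only permutes the outputs.
    """

    def __init__(self, cfg: ModelConfig, graph: nx.Graph, partition: Partition):
        super().__init__()
        self.cfg = cfg
        missing = [v for v in graph.nodes() if v not in partition.labels]
        if missing:
            raise ValueError(f"genes absent from partition: {missing[:5]}")
        if any(c >= cfg.k_clusters or c < 0 for c in partition.labels.values()):
            raise ValueError("partition labels must lie in [0, k_clusters)")
        init_rng = np.random.default_rng(cfg.seed)
        self.nodes = sorted(map(str, graph.nodes()))
        self.edges = {frozenset((str(u), str(v))) for u, v in graph.edges() if u != v}
        self.cluster_of = {str(v): int(c) for v, c in partition.labels.items()}
        self.mol_encoder = MolecularEncoder(init_rng, cfg)
        self.gene_encoder = GeneEncoder(init_rng, cfg, self.nodes)
        self.cross = CrossAttention(init_rng, cfg)
        self.scorer = _ScorerMLP(init_rng, cfg.d_g, cfg.dropout_p, cfg.leaky_slope)
        self.uncertainty_head = _ScorerMLP(init_rng, cfg.d_g, cfg.dropout_p, cfg.leaky_slope)
        self.gene_fc1 = Linear(init_rng, cfg.d_g, cfg.gene_head_hidden)
        self.gene_fc2 = Linear(init_rng, cfg.gene_head_hidden, 1)
        self.dec_fp1 = Linear(init_rng, cfg.d_m, cfg.d_m)
        self.dec_fp2 = Linear(init_rng, cfg.d_m, cfg.n_fp)
        self.dec_desc1 = Linear(init_rng, cfg.d_m, cfg.d_m)
        self.dec_desc2 = Linear(init_rng, cfg.d_m, cfg.n_desc)
        self.rng = np.random.default_rng(cfg.seed + 1)

    # -- structural helpers -------------------------------------------------
    def seed_dropout(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def _adj_mask(self, nodes: list) -> np.ndarray:
        index = {str(v): i for i, v in enumerate(nodes)}
        m = len(nodes)
        mask = np.zeros((m, m), dtype=bool)
        for e in self.edges:
            u, v = tuple(e)
            if u in index and v in index:
                mask[index[u], index[v]] = True
                mask[index[v], index[u]] = True
        return mask

    def _cluster_onehot(self, nodes: list) -> np.ndarray:
        onehot = np.zeros((len(nodes), self.cfg.k_clusters))
        for i, v in enumerate(nodes):
            onehot[i, self.cluster_of[str(v)]] = 1.0
        return onehot

    # -- forward pieces ------------------------------------------------------
    def encode_molecules(self, fp: np.ndarray, desc_std: np.ndarray, force_dropout=False) -> Tensor:
        if fp.shape[1] != self.cfg.n_fp or desc_std.shape[1] != self.cfg.n_desc:
            raise ValueError(
                f"feature widths ({fp.shape[1]}, {desc_std.shape[1]}) do not match config "
                f"({self.cfg.n_fp}, {self.cfg.n_desc})"
            )
        return self.mol_encoder(Tensor(fp.astype(float)), Tensor(desc_std), self.rng, force_dropout)

    def encode_genes(self, nodes: list | None = None, force_dropout=False):
        nodes = [str(v) for v in (nodes if nodes is not None else self.nodes)]
        unknown = [v for v in nodes if v not in self.gene_encoder.index]
        if unknown:
            raise ValueError(f"unknown gene(s): {unknown[:5]}")
        adj = self._adj_mask(nodes)
        onehot = self._cluster_onehot(nodes)
        return self.gene_encoder(nodes, adj, onehot, self.rng, force_dropout)

    def score_interaction(self, fused: Tensor, force_dropout=False):
        if fused.shape[-1] != 2 * self.cfg.d_g:
            raise ValueError(f"fused width {fused.shape[-1]} != {2 * self.cfg.d_g}")
        s = self.scorer(fused, self.rng, force_dropout).sigmoid()
        raw_u = self.uncertainty_head(fused, self.rng, force_dropout)
        if self.cfg.aleatoric_activation == "sigmoid":
            u = raw_u.sigmoid() * self.cfg.uncertainty_scale
        else:
            u = raw_u.softplus()
        return s.reshape(-1), u.reshape(-1)

    def gene_logits(self, z: Tensor) -> Tensor:
        h = _leaky(self.gene_fc1(z), self.cfg.leaky_slope)
        return self.gene_fc2(h).reshape(-1)

    def reconstruct(self, h_mol: Tensor):
        fp_logits = self.dec_fp2(_leaky(self.dec_fp1(h_mol), self.cfg.leaky_slope))
        desc_hat = self.dec_desc2(_leaky(self.dec_desc1(h_mol), self.cfg.leaky_slope))
        return fp_logits, desc_hat

    def forward_pairs(self, fp: np.ndarray, desc_std: np.ndarray, gene_ids: list,
                      force_dropout=False):
        """Score a batch of (drug, gene) pairs; row i pairs drug i with gene_ids[i].

        Gene embeddings are always computed on the full graph, so batch
        composition cannot change a pair's score in evaluation mode.
        """
        h_mol = self.encode_molecules(fp, desc_std, force_dropout)
        z_all, _ = self.encode_genes(force_dropout=force_dropout)
        rows = np.array([self.gene_encoder.index[str(g)] for g in gene_ids])
        z = z_all.take_rows(rows)
        fused, a_dg, a_gd = self.cross(h_mol, z, self.rng, force_dropout)
        s, u = self.score_interaction(fused, force_dropout)
        return {"score": s, "aleatoric": u, "h_mol": h_mol, "z_all": z_all,
                "fused": fused, "attn_drug_to_gene": a_dg, "attn_gene_to_drug": a_gd}

    # -- MC-dropout inference ------------------------------------------------
    def predict_mc(self, fp: np.ndarray, desc_std: np.ndarray, gene_ids: list,
                   t_passes: int | None = None, seed: int = 0):
        """Mean score, population MC variance, and mean aleatoric u over
        ``t_passes`` stochastic forward passes with dropout kept active."""
        t_passes = t_passes if t_passes is not None else self.cfg.mc_passes
        if t_passes < 1:
            raise ValueError("t_passes must be >= 1")
        was_training = self.training
        self.eval()
        self.seed_dropout(seed)
        scores, us = [], []
        with no_grad():
            for _ in range(t_passes):
                out = self.forward_pairs(fp, desc_std, gene_ids, force_dropout=True)
                scores.append(out["score"].numpy().copy())
                us.append(out["aleatoric"].numpy().copy())
        self.train(was_training)
        scores = np.array(scores)
        var = scores.var(axis=0)
        var[np.ptp(scores, axis=0) == 0.0] = 0.0  # identical passes: exact zero
        return scores.mean(axis=0), var, np.array(us).mean(axis=0)

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        import json

        state = self.state_dict()
        meta = {
            "config": self.cfg.to_dict(),
            "nodes": self.nodes,
            "edges": sorted(sorted(e) for e in self.edges),
            "clusters": self.cluster_of,
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "DTIModel":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        g = nx.Graph()
        g.add_nodes_from(meta["nodes"])
        g.add_edges_from(meta["edges"])
        part = Partition(labels={k: int(v) for k, v in meta["clusters"].items()}, q=float("nan"))
        model = cls(ModelConfig(**meta["config"]), g, part)
        model.load_state_dict(state)
        return model
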