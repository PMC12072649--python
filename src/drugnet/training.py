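"""Three-term objective, stratified splitting, Adam training loop, metrics.

The composite objective is ``L_total = L_DTI + L_gene + L_recon`` with

* ``L_DTI   = sum BCE(s, y) / u + lambda_u * sum log u`` — uncertainty-
  attenuated interaction loss: high-``u`` pairs are down-weighted while
  ``lambda_u * log u`` keeps the model from inflating ``u`` everywhere;
* ``L_gene  = lambda_g * sum BCE(sigmoid(Theta(z_j)), y_j)`` — auxiliary
  disease-gene classification on the gene embeddings;
* ``L_recon`` — molecular autoencoding, either BCE (fingerprint) + MSE
  (descriptors) (default, ``variant="bce_mse"``) or the L1 + squared-L2
  form (``variant="l1_l2"``).

Training uses Adam (lr 1e-4, batch 64, L2 weight decay 1e-5 by default)
with early stopping on validation AUROC, patience 10, and an optional
self-supervised reconstruction pretraining phase weighted 0.3.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from drugnet.model import DTIModel
from drugnet.nn import Adam, Tensor

_U_FLOOR = 1e-6  # clamp for u in the DTI loss denominator
_P_EPS = 1e-7    # probability clamp inside BCE


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 1e-5
    patience: int = 10
    max_epochs: int = 100
    lambda_u: float = 0.1
    lambda_g: float = 1.0
    lambda_r: float = 1.0
    lambda_pretrain: float = 0.3
    pretrain_epochs: int = 0
    recon_variant: str = "bce_mse"
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_u, self.lambda_g, self.lambda_r) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def to_dict(self):
        return asdict(self)


def split_dataset(dataset: pd.DataFrame, fractions=(0.7, 0.1, 0.2), seed: int = 0) -> pd.DataFrame:
    """Label-stratified random pair-level split into train/val/test.

    Split sizes are exact at the dataset level (largest-remainder
    rounding); stratification allocates each label class proportionally.
    Adds a ``split`` column; reproducible given ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive numbers summing to 1")
    n = len(dataset)
    sizes = [int(np.floor(f * n)) for f in fractions]
    remainders = [f * n - s for f, s in zip(fractions, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1
    if min(sizes) == 0:
        raise ValueError(f"split of {n} rows at {fractions} leaves an empty part")
    rng = np.random.default_rng(seed)
    tags = np.empty(n, dtype=object)
    quotas = list(sizes)
    # per-class proportional allocation, spill-over to the fullest remaining part
    order_parts = ["train", "val", "test"]
    labels = dataset["label"].to_numpy()
    class_indices = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    assigned = [0, 0, 0]
    for idx in class_indices:
        idx = rng.permutation(idx)
        want = [f * len(idx) for f in fractions]
        take = [int(np.floor(w)) for w in want]
        rem = [w - t for w, t in zip(want, take)]
        while sum(take) < len(idx):
            # prefer the part with the largest fractional remainder that still has quota
            candidates = sorted(range(3), key=lambda i: -rem[i])
            for i in candidates:
                if assigned[i] + take[i] < quotas[i]:
                    take[i] += 1
                    rem[i] = -1
                    break
            else:  # pragma: no cover
                take[int(np.argmax(rem))] += 1
        # clip to global quotas
        for i in range(3):
            take[i] = min(take[i], quotas[i] - assigned[i])
        while sum(take) < len(idx):
            for i in range(3):
                if assigned[i] + take[i] < quotas[i]:
                    take[i] += 1
                    break
        start = 0
        for i, part in enumerate(order_parts):
            tags[idx[start:start + take[i]]] = part
            start += take[i]
            assigned[i] += take[i]
    out = dataset.copy()
    out["split"] = tags
    return out


# -- losses -------------------------------------------------------------------

def _bce_elementwise(p: Tensor, y: np.ndarray) -> Tensor:
    p = p.clamp(_P_EPS, 1.0 - _P_EPS)
    y_t = Tensor(np.asarray(y, dtype=float))
    return -(y_t * p.log() + (1.0 - y_t) * (1.0 - p).log())


def loss_dti(scores: Tensor, labels: np.ndarray, uncertainties: Tensor, lambda_u: float) -> Tensor:
    """Uncertainty-attenuated BCE: sum BCE(s,y)/u + lambda_u * sum log u."""
    if not (np.isfinite(scores.numpy()).all() and np.isfinite(uncertainties.numpy()).all()):
        raise ValueError("NaN/inf in scores or uncertainties")
    u = uncertainties.clamp(_U_FLOOR, None)
    bce = _bce_elementwise(scores, labels)
    return (bce / u).sum() + lambda_u * u.log().sum()


def loss_gene(gene_logits: Tensor, gene_labels: np.ndarray, lambda_g: float) -> Tensor:
    """lambda_g * sum BCE(sigmoid(logit_j), y_j) over genes."""
    if len(gene_labels) != gene_logits.shape[0]:
        raise ValueError("one label per gene required")
    return lambda_g * _bce_elementwise(gene_logits.sigmoid(), gene_labels).sum()


def loss_recon(fp_out: Tensor, desc_out: Tensor, fp_true: np.ndarray, desc_true: np.ndarray,
               lambda_r: float, variant: str = "bce_mse") -> Tensor:
    """Molecular autoencoding loss (mean over the batch).

    ``bce_mse``: BCE of sigmoid(fingerprint logits) + MSE of descriptors.
    ``l1_l2``: L1 fingerprint residual + squared-L2 descriptor residual.
    """
    fp_t = Tensor(np.asarray(fp_true, dtype=float))
    d_t = Tensor(np.asarray(desc_true, dtype=float))
    b = max(fp_out.shape[0], 1)
    if variant == "bce_mse":
        fp_term = _bce_elementwise(fp_out.sigmoid(), fp_true).sum(axis=-1)
        desc_term = ((desc_out - d_t) ** 2).mean(axis=-1)
    elif variant == "l1_l2":
        fp_term = (fp_out - fp_t).abs().sum(axis=-1)
        desc_term = ((desc_out - d_t) ** 2).sum(axis=-1)
    else:
        raise ValueError(f"unknown reconstruction variant {variant!r}")
    return lambda_r * (fp_term + desc_term).sum() * (1.0 / b)


# -- metrics ------------------------------------------------------------------

def f1_score_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """AUROC (rank statistic) plus thresholded precision/recall/F1.

    Single-class label vectors get AUROC = NaN (reported as NA downstream).
    """
    labels = np.asarray(labels)
    pred = (np.asarray(scores) >= threshold).astype(int)
    auroc = float("nan") if len(np.unique(labels)) < 2 else float(roc_auc_score(labels, scores))
    precision = float(precision_score(labels, pred, zero_division=0))
    recall = float(recall_score(labels, pred, zero_division=0))
    return {
        "auroc": auroc,
        "precision": precision,
        "recall": recall,
        "f1": f1_score_from(precision, recall),
    }


# -- training loop ------------------------------------------------------------

@dataclass
class TrainResult:
    history: pd.DataFrame
    best_epoch: int
    best_val_auroc: float
    best_state: dict = field(repr=False, default=None)


class PairData:
    """Featurized interaction dataset: aligned drug features and gene ids."""

    def __init__(self, interactions: pd.DataFrame, drug_ids: list,
                 fingerprints: np.ndarray, descriptors_std: np.ndarray,
                 gene_labels: dict):
        self.table = interactions.reset_index(drop=True)
        self.drug_row = {str(d): i for i, d in enumerate(drug_ids)}
        unknown = sorted(set(self.table["drug_id"].astype(str)) - set(self.drug_row))
        if unknown:
            raise ValueError(f"interaction table references unfeaturized drug(s): {unknown[:5]}")
        self.fp = fingerprints
        self.desc = descriptors_std
        self.gene_labels = dict(gene_labels)

    def batch(self, rows: np.ndarray):
        sub = self.table.iloc[rows]
        drug_idx = np.array([self.drug_row[str(d)] for d in sub["drug_id"]])
        return (self.fp[drug_idx], self.desc[drug_idx],
                list(sub["gene_id"].astype(str)), sub["label"].to_numpy())

    def rows_for(self, split: str) -> np.ndarray:
        return np.flatnonzero((self.table["split"] == split).to_numpy())


def _predict_split(model: DTIModel, data: PairData, rows: np.ndarray, batch_size: int) -> np.ndarray:
    from drugnet.nn import no_grad

    model.eval()
    out = np.empty(len(rows))
    with no_grad():
        for start in range(0, len(rows), batch_size):
            chunk = rows[start:start + batch_size]
            fp, desc, genes, _ = data.batch(chunk)
            res = model.forward_pairs(fp, desc, genes)
            out[start:start + len(chunk)] = res["score"].numpy()
    model.train()
    return out


def train(model: DTIModel, data: PairData, cfg: TrainConfig) -> TrainResult:
    """Minimize the composite objective with Adam and early stopping.

    Monitors validation AUROC; returns per-epoch history and restores the
    best-validation weights on the model before returning.
    """
    train_rows = data.rows_for("train")
    val_rows = data.rows_for("val")
    if len(train_rows) == 0 or len(val_rows) == 0:
        raise ValueError("dataset must contain non-empty train and val splits")
    if data.table.iloc[train_rows]["label"].sum() == 0:
        raise ValueError("no positive labels in the training split")
    rng = np.random.default_rng(cfg.seed)
    model.seed_dropout(cfg.seed + 12345)
    model.train()
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                     weight_decay=cfg.weight_decay)
    gene_y = np.array([data.gene_labels[g] for g in model.nodes])

    # optional self-supervised warm-up on the drug library (reconstruction only)
    for _ in range(cfg.pretrain_epochs):
        perm = rng.permutation(len(data.fp))
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            optimizer.zero_grad()
            h = model.encode_molecules(data.fp[idx].astype(float), data.desc[idx])
            fp_out, desc_out = model.reconstruct(h)
            loss = cfg.lambda_pretrain * loss_recon(
                fp_out, desc_out, data.fp[idx], data.desc[idx], cfg.lambda_r, cfg.recon_variant)
            loss.backward()
            optimizer.step()

    history = []
    best_val, best_epoch, best_state = -np.inf, -1, None
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_rows)
        epoch_losses = []
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            fp, desc, genes, y = data.batch(idx)
            optimizer.zero_grad()
            out = model.forward_pairs(fp, desc, genes)
            l_dti = loss_dti(out["score"], y, out["aleatoric"], cfg.lambda_u)
            l_gene = loss_gene(model.gene_logits(out["z_all"]), gene_y, cfg.lambda_g)
            fp_out, desc_out = model.reconstruct(out["h_mol"])
            l_rec = loss_recon(fp_out, desc_out, fp, desc, cfg.lambda_r, cfg.recon_variant)
            total = l_dti * (1.0 / len(idx)) + l_gene * (1.0 / len(gene_y)) + l_rec
            total.backward()
            optimizer.step()
            epoch_losses.append(float(total.numpy()))
        val_scores = _predict_split(model, data, val_rows, cfg.batch_size)
        val_metrics = evaluate_scores(val_scores, data.table.iloc[val_rows]["label"].to_numpy())
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "val_auroc": val_metrics["auroc"]})
        if np.isfinite(val_metrics["auroc"]) and val_metrics["auroc"] > best_val:
            best_val, best_epoch = val_metrics["auroc"], epoch
            best_state = copy.deepcopy(model.state_dict())
        if epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainResult(history=pd.DataFrame(history), best_epoch=best_epoch,
                       best_val_auroc=best_val, best_state=best_state)


def evaluate(model: DTIModel, data: PairData, split: str = "test",
             batch_size: int = 64, threshold: float = 0.5) -> dict:
    rows = data.rows_for(split)
    if len(rows) == 0:
        raise ValueError(f"split {split!r} is empty")
    scores = _predict_split(model, data, rows, batch_size)
    model.eval()
    return evaluate_scores(scores, data.table.iloc[rows]["label"].to_numpy(), threshold)
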