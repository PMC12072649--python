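"""Library-scale screening: MC-dropout prediction, per-gene z-normalization,
uncertainty filtering with relaxation, ranking, and multi-target extraction.

Ranking aggregates over the target set G_target:

    Rank(d) = mean_g s_bar(d, g) - lambda_penalty * mean_g sqrt(u^2 + sigma^2)

i.e. mean interaction affinity minus a penalty on total (aleatoric +
epistemic) uncertainty. The uncertainty-filter operand is ``u + sqrt(sigma^2)``
capped at 1; the filter keeps records below tau = 0.5 and relaxes to 0.7
when fewer than ``min_pass`` drugs survive. z-scores and rank percentiles
are computed per target gene across the screened library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from drugnet.model import DTIModel


def screen_library(model: DTIModel, drug_ids: list, fingerprints: np.ndarray,
                   descriptors_std: np.ndarray, targets: dict,
                   batch_size: int = 64, t_passes: int = 10, seed: int = 0) -> pd.DataFrame:
    """One prediction record per (drug, target gene).

    ``targets`` maps community label -> ordered gene list (a TargetSet).
    Returns a DataFrame with columns drug_id, gene_id, cluster, mean_score,
    mc_variance, aleatoric, raw_score; deterministic given ``seed``.
    """
    genes = [(g, c) for c, gene_list in sorted(targets.items()) for g in gene_list]
    if not genes:
        raise ValueError("empty target set")
    records = []
    n_genes = len(genes)
    gene_names = [g for g, _ in genes]
    for start in range(0, len(drug_ids), batch_size):
        ids = drug_ids[start:start + batch_size]
        fp = np.repeat(fingerprints[start:start + batch_size], n_genes, axis=0)
        desc = np.repeat(descriptors_std[start:start + batch_size], n_genes, axis=0)
        pair_genes = gene_names * len(ids)
        mean_s, var_s, u = model.predict_mc(
            fp, desc, pair_genes, t_passes=t_passes,
            seed=seed + 7919 * (start // batch_size))
        for j, d in enumerate(ids):
            for k, (gene, cluster) in enumerate(genes):
                flat = j * n_genes + k
                records.append((str(d), str(gene), int(cluster), float(mean_s[flat]),
                                float(var_s[flat]), float(u[flat]), float(mean_s[flat])))
    return pd.DataFrame(records, columns=[
        "drug_id", "gene_id", "cluster", "mean_score", "mc_variance", "aleatoric", "raw_score"])


def normalize_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Per-target-gene z-scores (population std) and rank percentiles.

    percentile = 100 * (N - rank_index) / N with rank_index 0 for the best
    score, so the top record of each gene's library slice gets 100.0.
    Zero-variance slices get z = 0 with a warning.
    """
    if len(records) < 2:
        raise ValueError("normalization needs at least 2 records")
    out = records.copy()
    out["z"] = 0.0
    out["percentile"] = 0.0
    for gene, idx in out.groupby("gene_id").groups.items():
        x = out.loc[idx, "raw_score"].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0.0:
            warnings.warn(f"zero score variance for gene {gene}; z set to 0", stacklevel=2)
            z = np.zeros_like(x)
        else:
            z = (x - x.mean()) / sd
        n = len(x)
        order = np.argsort(-x, kind="stable")
        rank_index = np.empty(n, dtype=int)
        rank_index[order] = np.arange(n)
        out.loc[idx, "z"] = z
        out.loc[idx, "percentile"] = 100.0 * (n - rank_index) / n
    out["probability_pct"] = 100.0 * out["mean_score"]
    return out


def total_uncertainty(records: pd.DataFrame) -> np.ndarray:
    """Filter operand: u + sqrt(mc variance), capped at 1."""
    return np.minimum(records["aleatoric"] + np.sqrt(records["mc_variance"]), 1.0)


def filter_by_uncertainty(records: pd.DataFrame, tau: float = 0.5,
                          tau_relaxed: float = 0.7, min_pass: int = 10):
    """Keep records with total uncertainty < tau; if fewer than
    ``min_pass`` distinct drugs survive, re-filter at ``tau_relaxed``.

    Returns ``(filtered records, threshold applied)``.
    """
    if records.empty:
        return records.copy(), tau
    unc = total_uncertainty(records)
    kept = records[unc < tau]
    if kept["drug_id"].nunique() < min_pass:
        kept = records[unc < tau_relaxed]
        return kept.copy(), tau_relaxed
    return kept.copy(), tau


@dataclass
class RankingResult:
    table: pd.DataFrame  # drug_id, rank_score, mean_affinity, mean_uncertainty
    lambda_penalty: float


def rank_drugs(records: pd.DataFrame, targets: dict, lambda_penalty: float = 1.0) -> RankingResult:
    """Rank(d) = mean affinity - lambda_penalty * mean per-pair
    sqrt(aleatoric^2 + MC variance) over the full target set.

    Every (drug, target) pair must be present; ties break toward lower
    total uncertainty, then drug id.
    """
    target_genes = [g for _, gene_list in sorted(targets.items()) for g in gene_list]
    rows = []
    grouped = records.groupby("drug_id")
    for drug_id, sub in grouped:
        have = set(sub["gene_id"])
        missing = [g for g in target_genes if g not in have]
        if missing:
            raise ValueError(f"drug {drug_id}: missing target pair(s) {missing[:3]}")
        sub = sub.set_index("gene_id").loc[target_genes]
        affinity = float(sub["mean_score"].mean())
        unc = float(np.sqrt(sub["aleatoric"] ** 2 + sub["mc_variance"]).mean())
        rows.append((str(drug_id), affinity - lambda_penalty * unc, affinity, unc))
    table = pd.DataFrame(rows, columns=["drug_id", "rank_score", "mean_affinity", "mean_uncertainty"])
    table = table.sort_values(["rank_score", "mean_uncertainty", "drug_id"],
                              ascending=[False, True, True], kind="stable").reset_index(drop=True)
    return RankingResult(table=table, lambda_penalty=lambda_penalty)


def find_multitarget(records: pd.DataFrame, z_threshold: float = 2.8) -> pd.DataFrame:
    """Polypharmacology candidates: drugs with z > threshold on >= 2 target
    genes lying in >= 2 distinct network clusters.

    Output schema (one row per qualifying drug): Drug, Targets, z-Score
    (mean over qualifying pairs), Percentile, Probability, Uncertainty.
    """
    if "z" not in records.columns:
        raise ValueError("records must be normalized first (missing 'z')")
    rows = []
    for drug_id, sub in records.groupby("drug_id"):
        hits = sub[sub["z"] > z_threshold]
        if len(hits) < 2 or hits["cluster"].nunique() < 2:
            continue
        rows.append({
            "Drug": str(drug_id),
            "Targets": ",".join(sorted(hits["gene_id"])),
            "z-Score": float(hits["z"].mean()),
            "Percentile": float(hits["percentile"].mean()),
            "Probability": float(hits["probability_pct"].mean()),
            "Uncertainty": float(total_uncertainty(hits).mean()),
        })
    out = pd.DataFrame(rows, columns=["Drug", "Targets", "z-Score", "Percentile",
                                      "Probability", "Uncertainty"])
    return out.sort_values("z-Score", ascending=False, kind="stable").reset_index(drop=True)
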