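"""Dataset splitting, the three loss terms, training dynamics, metrics."""

import numpy as np
import pandas as pd
import pytest

from drugnet.nn import Tensor
from drugnet.training import (
    TrainConfig,
    evaluate,
    evaluate_scores,
    f1_score_from,
    loss_dti,
    loss_gene,
    loss_recon,
    split_dataset,
)


def _toy_dataset(n=1000, positive_rate=0.10, seed=0):
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < positive_rate).astype(int)
    return pd.DataFrame({
        "drug_id": [f"D{i % 50}" for i in range(n)],
        "gene_id": [f"G{i % 20}" for i in range(n)],
        "label": labels,
    })


class TestSplit:
    def test_exact_sizes(self):
        ds = split_dataset(_toy_dataset(1000), (0.7, 0.1, 0.2), seed=0)
        counts = ds["split"].value_counts()
        assert counts["train"] == 700 and counts["val"] == 100 and counts["test"] == 200

    def test_stratification_within_two_points(self):
        ds = split_dataset(_toy_dataset(1000, 0.10, seed=3), seed=1)
        overall = ds["label"].mean()
        for part in ("train", "val", "test"):
            rate = ds.loc[ds["split"] == part, "label"].mean()
            assert abs(rate - overall) <= 0.02

    def test_reproducible(self):
        a = split_dataset(_toy_dataset(), seed=9)
        b = split_dataset(_toy_dataset(), seed=9)
        assert (a["split"] == b["split"]).all()

    def test_each_pair_in_exactly_one_split(self):
        ds = split_dataset(_toy_dataset(300), seed=2)
        assert ds["split"].notna().all()
        assert set(ds["split"]) == {"train", "val", "test"}

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_toy_dataset(5), (0.7, 0.1, 0.2), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            split_dataset(_toy_dataset(), (0.5, 0.5, 0.5), seed=0)


class TestLosses:
    def test_unit_uncertainty_reduces_to_plain_bce(self):
        s = Tensor(np.array([0.8, 0.3]))
        y = np.array([1, 0])
        u = Tensor(np.ones(2))
        expected = -(np.log(0.8) + np.log(0.7))
        assert float(loss_dti(s, y, u, 0.1).numpy()) == pytest.approx(expected, abs=1e-9)

    def test_perfect_predictions_near_zero(self):
        eps = 1e-6
        s = Tensor(np.array([1 - eps, eps]))
        y = np.array([1, 0])
        assert float(loss_dti(s, y, Tensor(np.ones(2)), 0.1).numpy()) == pytest.approx(0.0, abs=1e-4)

    def test_dti_hand_case(self):
        """Two-pair case evaluated by hand: BCE/u + lambda_u * log u."""
        s, y, u, lam = np.array([0.9, 0.2]), np.array([1, 0]), np.array([0.5, 1.0]), 0.1
        expected = (-np.log(0.9) / 0.5 - np.log(0.8) / 1.0) + lam * (np.log(0.5) + np.log(1.0))
        got = loss_dti(Tensor(s), y, Tensor(u), lam)
        assert float(got.numpy()) == pytest.approx(expected, abs=1e-9)

    def test_dti_rejects_nan(self):
        with pytest.raises(ValueError, match="NaN"):
            loss_dti(Tensor(np.array([np.nan])), np.array([1]), Tensor(np.array([1.0])), 0.1)

    def test_gene_loss_weight_annihilation_and_hand_case(self):
        logits = Tensor(np.array([2.0, -1.0, 0.5]))
        y = np.array([1, 0, 1])
        assert float(loss_gene(logits, y, 0.0).numpy()) == 0.0
        p = 1 / (1 + np.exp(-np.array([2.0, -1.0, 0.5])))
        expected = -(np.log(p[0]) + np.log(1 - p[1]) + np.log(p[2]))
        assert float(loss_gene(logits, y, 1.0).numpy()) == pytest.approx(expected, abs=1e-9)

    def test_gene_loss_missing_labels_rejected(self):
        with pytest.raises(ValueError, match="one label per gene"):
            loss_gene(Tensor(np.zeros(3)), np.array([1, 0]), 1.0)

    def test_recon_zero_residual_and_weight_annihilation(self):
        fp = np.array([[1.0, 0.0, 1.0, 1.0]])
        d = np.array([[0.3, -0.7]])
        zero = loss_recon(Tensor(fp), Tensor(d), fp, d, 1.0, variant="l1_l2")
        assert float(zero.numpy()) == pytest.approx(0.0, abs=1e-12)
        off = loss_recon(Tensor(fp), Tensor(d + 1), fp, d, 0.0, variant="l1_l2")
        assert float(off.numpy()) == 0.0

    def test_recon_hand_case_both_variants(self):
        fp_logits = np.array([[2.0, -2.0, 0.0, 1.0]])
        fp_true = np.array([[1, 0, 0, 1]])
        d_out = np.array([[0.5, -0.5]])
        d_true = np.array([[0.0, 0.5]])
        sig = 1 / (1 + np.exp(-fp_logits[0]))
        bce = -(np.log(sig[0]) + np.log(1 - sig[1]) + np.log(1 - sig[2]) + np.log(sig[3]))
        mse = np.mean((d_out - d_true) ** 2)
        got = loss_recon(Tensor(fp_logits), Tensor(d_out), fp_true, d_true, 1.0, "bce_mse")
        assert float(got.numpy()) == pytest.approx(bce + mse, abs=1e-9)
        l1 = np.abs(fp_logits - fp_true).sum()
        l2 = ((d_out - d_true) ** 2).sum()
        got = loss_recon(Tensor(fp_logits), Tensor(d_out), fp_true, d_true, 1.0, "l1_l2")
        assert float(got.numpy()) == pytest.approx(l1 + l2, abs=1e-9)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            loss_recon(Tensor(np.zeros((1, 2))), Tensor(np.zeros((1, 2))),
                       np.zeros((1, 2)), np.zeros((1, 2)), 1.0, "bogus")


class TestMetrics:
    def test_perfect_separation(self):
        m = evaluate_scores(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert m["auroc"] == 1.0 and m["f1"] == 1.0

    def test_printed_precision_recall_give_printed_f1(self):
        """Harmonic mean of P=0.83, R=0.79 rounds to 0.81 at 2 decimals."""
        assert round(f1_score_from(0.83, 0.79), 2) == 0.81

    def test_random_scores_near_half_auroc(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, size=10000)
        m = evaluate_scores(scores, labels)
        assert m["auroc"] == pytest.approx(0.5, abs=0.02)

    def test_single_class_auroc_na(self):
        m = evaluate_scores(np.array([0.4, 0.6]), np.array([1, 1]))
        assert np.isnan(m["auroc"])

    def test_f1_identity(self):
        rng = np.random.default_rng(1)
        m = evaluate_scores(rng.random(200), rng.integers(0, 2, 200))
        p, r = m["precision"], m["recall"]
        if p + r > 0:
            assert m["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)


class TestTrainingDynamics:
    def test_loss_decreases_and_benchmark_auroc(self, trained_benchmark):
        """On the separable synthetic benchmark the training loss falls over
        the first epochs and held-out AUROC is high."""
        hist = trained_benchmark["result"].history
        assert hist["train_loss"].iloc[4] < hist["train_loss"].iloc[0]
        metrics = evaluate(trained_benchmark["model"], trained_benchmark["data"])
        assert metrics["auroc"] >= 0.85

    def test_early_stopping_contract(self, trained_benchmark):
        res = trained_benchmark["result"]
        last_epoch = res.history["epoch"].iloc[-1]
        assert last_epoch - res.best_epoch <= 10

    def test_identical_seeds_give_identical_history(self, tiny_study):
        from conftest import build_pair_data, desk_model_config
        from drugnet.model import DTIModel
        from drugnet.training import train

        histories = []
        for _ in range(2):
            data, _ = build_pair_data(tiny_study, seed=4)
            cfg = desk_model_config(tiny_study, seed=4, k_clusters=3, d_m=32, d_g=32,
                                    gat_heads=4, transformer_heads=4,
                                    cross_heads=4, cross_head_dim=8, gene_head_hidden=16)
            model = DTIModel(cfg, tiny_study.graph, tiny_study.partition)
            res = train(model, data, TrainConfig(max_epochs=3, seed=4))
            histories.append(res.history)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_no_positive_labels_rejected(self, tiny_study):
        from conftest import build_pair_data, desk_model_config
        from drugnet.model import DTIModel
        from drugnet.training import train

        data, _ = build_pair_data(tiny_study, seed=0)
        data.table.loc[data.table["split"] == "train", "label"] = 0
        cfg = desk_model_config(tiny_study, k_clusters=3, d_m=32, d_g=32,
                                gat_heads=4, transformer_heads=4,
                                cross_heads=4, cross_head_dim=8, gene_head_hidden=16)
        model = DTIModel(cfg, tiny_study.graph, tiny_study.partition)
        with pytest.raises(ValueError, match="no positive labels"):
            train(model, data, TrainConfig(max_epochs=1))
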