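"""Screening: normalization, uncertainty filtering, ranking, multi-target."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugnet.screening import (
    filter_by_uncertainty,
    find_multitarget,
    normalize_scores,
    rank_drugs,
    screen_library,
    total_uncertainty,
)


def _records(rows):
    return pd.DataFrame(rows, columns=[
        "drug_id", "gene_id", "cluster", "mean_score", "mc_variance", "aleatoric", "raw_score"])


@pytest.fixture()
def hand_records():
    """Four drugs against one gene, scores 1..4."""
    return _records([(f"d{i}", "g1", 0, s / 4, 0.0, 0.1, float(s))
                     for i, s in enumerate([1, 2, 3, 4])])


class TestScreenLibrary:
    def test_record_cardinality_and_bounds(self, tiny_study, tiny_model):
        targets = {0: ["G0000", "G0001"], 1: ["G0002"]}
        targets = {c: [g for g in gs if g in tiny_model.nodes] for c, gs in targets.items()}
        targets = {c: gs for c, gs in targets.items() if gs}
        desc = (tiny_study.drugs.descriptors - tiny_study.drugs.descriptors.mean(0)) \
            / tiny_study.drugs.descriptors.std(0)
        recs = screen_library(tiny_model, tiny_study.drugs.ids[:10],
                              tiny_study.drugs.fingerprints[:10], desc[:10],
                              targets, batch_size=4, t_passes=3, seed=0)
        n_targets = sum(len(v) for v in targets.values())
        assert len(recs) == 10 * n_targets
        assert (recs["aleatoric"] <= 0.5).all()

    def test_empty_target_set_rejected(self, tiny_study, tiny_model):
        with pytest.raises(ValueError, match="empty target set"):
            screen_library(tiny_model, [], np.zeros((0, 1)), np.zeros((0, 1)), {})


class TestNormalize:
    def test_hand_zscores_population_std(self, hand_records):
        out = normalize_scores(hand_records)
        assert np.allclose(sorted(out["z"]), [-1.3416407865, -0.4472135955,
                                              0.4472135955, 1.3416407865], atol=1e-9)

    def test_top_record_gets_percentile_100(self, hand_records):
        out = normalize_scores(hand_records)
        assert out.loc[out["raw_score"].idxmax(), "percentile"] == 100.0

    def test_mean_score_maps_to_zero_z(self):
        recs = _records([("a", "g", 0, 0.2, 0.0, 0.1, 1.0),
                         ("b", "g", 0, 0.4, 0.0, 0.1, 2.0),
                         ("c", "g", 0, 0.6, 0.0, 0.1, 3.0)])
        out = normalize_scores(recs)
        assert out.loc[out["raw_score"] == 2.0, "z"].iloc[0] == pytest.approx(0.0)

    @given(a=st.floats(min_value=0.1, max_value=10), b=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance_of_z(self, a, b):
        records = _records([(f"d{i}", "g1", 0, s / 4, 0.0, 0.1, float(s))
                            for i, s in enumerate([1, 2, 3, 4])])
        base = normalize_scores(records)
        shifted = records.copy()
        shifted["raw_score"] = a * shifted["raw_score"] + b
        out = normalize_scores(shifted)
        assert np.allclose(out["z"], base["z"], atol=1e-9)

    def test_zero_variance_warns(self):
        recs = _records([("a", "g", 0, 0.5, 0.0, 0.1, 1.0),
                         ("b", "g", 0, 0.5, 0.0, 0.1, 1.0)])
        with pytest.warns(UserWarning, match="zero score variance"):
            out = normalize_scores(recs)
        assert (out["z"] == 0).all()


class TestFilter:
    def test_all_pass_no_relaxation(self):
        recs = _records([(f"d{i}", "g", 0, 0.5, 0.0, 0.3, 0.5) for i in range(12)])
        kept, tau = filter_by_uncertainty(recs)
        assert len(kept) == 12 and tau == 0.5

    def test_relaxation_branch_fires(self):
        """5 drugs below 0.5 and 20 in (0.5, 0.7): relaxed filter keeps 25."""
        low = [(f"lo{i}", "g", 0, 0.5, 0.0, 0.4, 0.5) for i in range(5)]
        mid = [(f"mid{i}", "g", 0, 0.5, 0.0, 0.6, 0.5) for i in range(20)]
        kept, tau = filter_by_uncertainty(_records(low + mid), tau=0.5, tau_relaxed=0.7, min_pass=10)
        assert tau == 0.7 and kept["drug_id"].nunique() == 25

    def test_empty_input_passes_through(self):
        kept, _ = filter_by_uncertainty(_records([]))
        assert kept.empty

    def test_filtering_is_idempotent(self):
        rng = np.random.default_rng(0)
        recs = _records([(f"d{i}", "g", 0, 0.5, float(rng.random() * 0.1),
                          float(rng.random() * 0.5), 0.5) for i in range(30)])
        once, tau1 = filter_by_uncertainty(recs)
        twice, tau2 = filter_by_uncertainty(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_operand_capped_at_one(self):
        recs = _records([("d", "g", 0, 0.5, 4.0, 0.5, 0.5)])
        assert total_uncertainty(recs)[0] == 1.0


class TestRanking:
    @pytest.fixture()
    def three_drug_records(self):
        targets = {0: ["g1"], 1: ["g2"]}
        rows = [
            ("a", "g1", 0, 0.9, 0.01, 0.10, 0.9), ("a", "g2", 1, 0.7, 0.04, 0.20, 0.7),
            ("b", "g1", 0, 0.85, 0.00, 0.05, 0.85), ("b", "g2", 1, 0.78, 0.00, 0.05, 0.78),
            ("c", "g1", 0, 0.6, 0.09, 0.40, 0.6), ("c", "g2", 1, 0.5, 0.16, 0.30, 0.5),
        ]
        return _records(rows), targets

    def test_zero_penalty_orders_by_mean_score(self, three_drug_records):
        recs, targets = three_drug_records
        result = rank_drugs(recs, targets, lambda_penalty=0.0)
        means = recs.groupby("drug_id")["mean_score"].mean().sort_values(ascending=False)
        assert list(result.table["drug_id"]) == list(means.index)

    def test_no_uncertainty_rank_equals_mean_score(self):
        recs = _records([("a", "g1", 0, 0.7, 0.0, 0.0, 0.7),
                         ("a", "g2", 1, 0.5, 0.0, 0.0, 0.5)])
        result = rank_drugs(recs, {0: ["g1"], 1: ["g2"]}, lambda_penalty=1.0)
        assert result.table["rank_score"].iloc[0] == pytest.approx(0.6)

    def test_hand_case_matches_formula(self, three_drug_records):
        recs, targets = three_drug_records
        result = rank_drugs(recs, targets, lambda_penalty=1.0).table.set_index("drug_id")
        expected_a = (0.9 + 0.7) / 2 - (np.sqrt(0.1**2 + 0.01) + np.sqrt(0.2**2 + 0.04)) / 2
        assert result.loc["a", "rank_score"] == pytest.approx(expected_a, abs=1e-12)

    def test_penalty_monotone_for_most_uncertain_drug(self, three_drug_records):
        """Raising the penalty never improves the most-uncertain drug's position."""
        recs, targets = three_drug_records
        worst = rank_drugs(recs, targets, 0.0).table.set_index("drug_id")["mean_uncertainty"].idxmax()
        prev_pos = None
        for lam in (0.0, 0.5, 1.0, 2.0, 5.0):
            tab = rank_drugs(recs, targets, lam).table
            pos = tab.index[tab["drug_id"] == worst][0]
            if prev_pos is not None:
                assert pos >= prev_pos
            prev_pos = pos

    def test_missing_pair_named(self, three_drug_records):
        recs, targets = three_drug_records
        with pytest.raises(ValueError, match="missing target pair"):
            rank_drugs(recs.iloc[:-1], targets)


class TestMultiTarget:
    def test_two_clusters_included_same_cluster_excluded(self):
        rows = [
            ("hit", "g1", 0, 0.9, 0.0, 0.1, 0.9), ("hit", "g2", 1, 0.9, 0.0, 0.1, 0.9),
            ("near", "g1", 0, 0.85, 0.0, 0.1, 0.85), ("near", "g3", 0, 0.85, 0.0, 0.1, 0.85),
        ]
        recs = _records(rows)
        recs["z"] = [3.0, 3.0, 3.0, 3.0]
        recs["percentile"] = 100.0
        recs["probability_pct"] = 100 * recs["mean_score"]
        out = find_multitarget(recs, z_threshold=2.8)
        assert list(out["Drug"]) == ["hit"]
        assert out.loc[0, "Targets"] == "g1,g2"

    def test_requires_normalized_records(self, hand_records):
        with pytest.raises(ValueError, match="normalized"):
            find_multitarget(hand_records)

    def test_planted_polypharmacology_drug_found_exactly(self):
        """On ground-truth probability records the planted drug is the sole hit."""
        from drugnet.synthetic import SyntheticConfig, generate_study
        from drugnet.synthetic import gene_latents, _calibrate_beta

        cfg = SyntheticConfig(seed=2)
        study = generate_study(cfg)
        lat = gene_latents(study.partition, cfg, 2)
        genes = sorted(lat)
        gm = np.array([lat[g] for g in genes])
        logits = cfg.alpha * study.drugs.latents @ gm.T
        beta = _calibrate_beta(logits.ravel(), cfg.positive_rate)
        p = 1.0 / (1.0 + np.exp(-(logits + beta)))
        rows = [(d, g, study.partition.labels[g], p[i, j], 0.0, 0.1, p[i, j])
                for i, d in enumerate(study.drugs.ids) for j, g in enumerate(genes)]
        recs = normalize_scores(_records(rows))
        out = find_multitarget(recs, z_threshold=2.8)
        assert list(out["Drug"]) == study.drugs.planted_ids
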