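import math

import numpy as np
import pytest

from metabiomark.data_model import FeatureTable
from metabiomark.ranking import fit_differentials
from metabiomark.synthetic_data import (
    PlantedEffect,
    StudySpec,
    default_feature_ids,
    derive_functional_profiles,
    generate_case_control_study,
    generate_fmt_cohort,
    generate_link_table,
    generate_multi_study,
)

SPECS_3D_2V = [
    StudySpec("d1", 40, 40, "discovery"),
    StudySpec("d2", 40, 40, "discovery"),
    StudySpec("d3", 40, 40, "discovery"),
    StudySpec("v1", 40, 40, "validation"),
    StudySpec("v2", 40, 40, "validation"),
]


class TestPlantedEffect:
    def test_requires_studies(self):
        with pytest.raises(ValueError, match="non-empty"):
            PlantedEffect("f", 1.0, frozenset())

    def test_requires_finite(self):
        with pytest.raises(ValueError, match="finite"):
            PlantedEffect("f", math.inf, frozenset({"s"}))


class TestCaseControl:
    def test_seeding_contract_bit_identical(self):
        a = generate_case_control_study(10, 10, 30, [], seed=7)
        b = generate_case_control_study(10, 10, 30, [], seed=7)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert [r.sample_id for r in a[1]] == [r.sample_id for r in b[1]]

    def test_different_seed_differs(self):
        a = generate_case_control_study(10, 10, 30, [], seed=7)
        b = generate_case_control_study(10, 10, 30, [], seed=8)
        assert not np.array_equal(a[0].values, b[0].values)

    def test_column_sums_are_integer_depths(self):
        table, _, _ = generate_case_control_study(15, 15, 40, [], depth_mean=5000, seed=0)
        sums = table.values.sum(axis=0)
        np.testing.assert_array_equal(sums, sums.round())
        assert np.all(sums >= 1)

    def test_unknown_effect_feature_rejected(self):
        effect = PlantedEffect("nope", 1.0, frozenset({"study1"}))
        with pytest.raises(ValueError, match="unknown feature"):
            generate_case_control_study(5, 5, 10, [effect])

    def test_effect_shifts_mean_abundance(self):
        # oracle: the softmax expectation with a positive logit shift is larger
        effect = PlantedEffect("sp0001", math.log(4.0), frozenset({"study1"}))
        table, records, _ = generate_case_control_study(
            100, 100, 50, [effect], depth_mean=5000, seed=3
        )
        rel = table.values / table.values.sum(axis=0, keepdims=True)
        is_r = np.array([r.response == "R" for r in records])
        row = table.feature_index("sp0001")
        assert rel[row, is_r].mean() > rel[row, ~is_r].mean()

    def test_null_differentials_small(self):
        table, records, _ = generate_case_control_study(
            20, 20, 50, [], depth_mean=8000, seed=4, sample_noise_sigma=0.1
        )
        res = fit_differentials(table, records, seed=0)
        diffs = np.abs(res.differential_array())
        spread = diffs.std()
        assert np.mean(diffs < 3 * max(spread, 0.05)) >= 0.95


class TestMultiStudy:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            generate_multi_study(SPECS_3D_2V, {"sp0001"}, {"sp0001"}, seed=0)

    def test_truth_consolidated_set_by_construction(self):
        bundles, truth = generate_multi_study(
            SPECS_3D_2V, {"sp0001", "sp0002"}, {"sp0003"}, seed=0, n_features=50
        )
        assert truth.consistent_positive == {"sp0001", "sp0002"}
        assert truth.inconsistent == {"sp0003"}
        assert set(bundles) == {"d1", "d2", "d3", "v1", "v2"}
        # inconsistent features carry both a positive and a negative effect
        signs = {e.log_fold > 0 for e in truth.effects if e.feature_id == "sp0003"}
        assert signs == {True, False}

    def test_no_effects_truth_empty(self):
        _, truth = generate_multi_study(SPECS_3D_2V[:3], set(), set(), seed=1, n_features=30)
        assert truth.consistent_positive == set()

    def test_consolidation_recovery_monte_carlo(self):
        # oracle: repeat generation + consolidation and tally precision/recall
        from metabiomark.consistency import consolidate
        from metabiomark.ranking import call_top_k

        planted = {"sp0001", "sp0002"}
        precisions, recalls = [], []
        for seed in range(20):
            bundles, _ = generate_multi_study(
                SPECS_3D_2V[:3],
                planted,
                set(),
                seed=seed,
                n_features=100,
                effect_size=math.log(3.0),
            )
            calls = []
            for bundle in bundles.values():
                res = fit_differentials(bundle.table, bundle.records, seed=seed)
                # k small relative to the feature count keeps chance
                # co-occurrence of null features across studies low
                calls.extend(call_top_k(res, 3))
            got = set(consolidate(calls).consolidated_rmi)
            tp = len(got & planted)
            precisions.append(tp / len(got) if got else 1.0)
            recalls.append(tp / len(planted))
        assert np.mean(precisions) >= 0.8
        assert np.mean(recalls) >= 0.8


class TestFmtCohort:
    def test_baseline_required(self):
        with pytest.raises(ValueError, match="baseline"):
            generate_fmt_cohort(2, 4, [14, 42], 0.5, 0.5, seed=0)

    def test_full_engraftment_limiting_case(self):
        table, records, truth = generate_fmt_cohort(
            3, 6, [-7, 14], 1.0, 1.0, seed=0, n_features=60
        )
        post = {r.sample_id: r for r in records if r.role == "recipient" and r.timepoint_days > 0}
        for sample_id, rec in post.items():
            col = table.column(sample_id)
            for i, f in enumerate(table.feature_ids):
                if truth.engraftment_truth[(rec.subject_id, f)] == "donor_derived":
                    assert col[i] > 0

    def test_zero_engraftment_limiting_case(self):
        _, _, truth = generate_fmt_cohort(3, 6, [-7, 14], 0.0, 0.0, seed=0, n_features=60)
        assert all(v != "donor_derived" for v in truth.engraftment_truth.values())

    def test_probability_bounds_checked(self):
        with pytest.raises(ValueError, match="probabilities"):
            generate_fmt_cohort(2, 4, [-7, 14], 1.5, 0.5, seed=0)

    def test_truth_consistent_with_tables(self):
        table, records, truth = generate_fmt_cohort(3, 8, [-7, 14], 0.7, 0.3, seed=2)
        donor_cols = {
            r.subject_id: table.column(r.sample_id) for r in records if r.role == "donor"
        }
        recipients = {r.subject_id: r for r in records if r.role == "recipient"}
        for (recipient, feature), label in truth.engraftment_truth.items():
            if label == "donor_derived":
                donor = recipients[recipient].donor
                assert donor_cols[donor][table.feature_index(feature)] > 0

    def test_response_modulated_richness(self):
        # oracle: direct tally of truth labels across seeds
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            _, records, truth = generate_fmt_cohort(
                4, 30, [-7, 14], 0.9, 0.4, seed=seed, n_features=100
            )
            response = {r.subject_id: r.response for r in records if r.role == "recipient"}
            richness = {}
            for (recipient, _), label in truth.engraftment_truth.items():
                if label == "donor_derived":
                    richness[recipient] = richness.get(recipient, 0) + 1
            r_vals = [richness.get(s, 0) for s, resp in response.items() if resp == "R"]
            nr_vals = [richness.get(s, 0) for s, resp in response.items() if resp == "NR"]
            from metabiomark.coda_stats import wilcoxon_rank_sum

            if np.mean(r_vals) > np.mean(nr_vals) and wilcoxon_rank_sum(r_vals, nr_vals) < 0.05:
                wins += 1
        assert wins >= 0.8 * n_seeds


class TestFunctionalProfiles:
    def taxon_table(self):
        return FeatureTable(
            np.array([[2.0, 4.0], [3.0, 1.0]]), ["tA", "tB"], ["s1", "s2"]
        )

    def test_unlinked_gene_group_all_zero(self):
        out = derive_functional_profiles(
            self.taxon_table(), {("tA", "k1")}, gene_group_ids=["k1", "k2"]
        )
        assert list(out.values[out.feature_index("k2")]) == [0.0, 0.0]

    def test_single_taxon_unit_weights(self):
        out = derive_functional_profiles(self.taxon_table(), {("tA", "k1"), ("tA", "k2")})
        np.testing.assert_array_equal(out.values[0], [2.0, 4.0])
        np.testing.assert_array_equal(out.values[1], [2.0, 4.0])

    def test_weighted_sum(self):
        # values 2 and 3 with weights 1 and 2 -> 2*1 + 3*2 = 8
        out = derive_functional_profiles(
            self.taxon_table(),
            {("tA", "k1"), ("tB", "k1")},
            copy_weights={("tA", "k1"): 1.0, ("tB", "k1"): 2.0},
        )
        assert out.values[0, 0] == pytest.approx(8.0)
        assert out.feature_kind == "gene_group"

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative copy weight"):
            derive_functional_profiles(
                self.taxon_table(), {("tA", "k1")}, copy_weights={("tA", "k1"): -1.0}
            )

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="unknown taxon"):
            derive_functional_profiles(self.taxon_table(), {("nope", "k1")})


class TestLinkTable:
    def test_deterministic(self):
        taxa = default_feature_ids(20)
        assert generate_link_table(taxa, 30, seed=5) == generate_link_table(taxa, 30, seed=5)

    def test_every_gene_group_linked(self):
        taxa = default_feature_ids(10)
        pairs = generate_link_table(taxa, 25, seed=0)
        assert {g for _, g in pairs} == set(default_feature_ids(25, kind="gene_group"))
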