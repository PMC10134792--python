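import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabiomark.coda_stats import (
    aitchison_distance,
    aitchison_distance_matrix,
    assess_log_ratio,
    benjamini_hochberg,
    bray_curtis,
    log_ratio,
    permanova,
    wilcoxon_rank_sum,
)
from metabiomark.data_model import FeatureTable, SampleRecord


def exact_rank_sum_p(a, b):
    """Brute-force two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mean_u = n_a * len(b) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestLogRatio:
    def make_table(self, cols):
        values = np.array(cols, dtype=float).T
        return FeatureTable(
            values,
            [f"f{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])],
        )

    def test_equal_sums_give_zero(self):
        table = self.make_table([[10.0, 10.0]])
        res = log_ratio(table, {"f0"}, {"f1"})
        assert res.per_sample_log_ratio["s0"] == pytest.approx(0.0)

    def test_hand_value(self):
        # numerator {3,5}, denominator {2,2} -> ln(8/4)
        table = self.make_table([[3.0, 5.0, 2.0, 2.0]])
        res = log_ratio(table, {"f0", "f1"}, {"f2", "f3"})
        assert res.per_sample_log_ratio["s0"] == pytest.approx(math.log(2.0))

    def test_scale_invariance(self):
        table = self.make_table([[3.0, 5.0, 2.0, 2.0], [21.0, 35.0, 14.0, 14.0]])
        res = log_ratio(table, {"f0", "f1"}, {"f2", "f3"})
        assert res.per_sample_log_ratio["s0"] == pytest.approx(res.per_sample_log_ratio["s1"])

    def test_zero_sum_dropped_and_counted(self):
        table = self.make_table([[0.0, 0.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0]])
        res = log_ratio(table, {"f0", "f1"}, {"f2", "f3"})
        assert res.n_dropped == 1
        assert "s0" not in res.per_sample_log_ratio
        assert "s1" in res.per_sample_log_ratio

    def test_overlap_rejected(self):
        table = self.make_table([[1.0, 1.0]])
        with pytest.raises(ValueError, match="overlap"):
            log_ratio(table, {"f0"}, {"f0"})

    def test_no_feature_in_table_rejected(self):
        table = self.make_table([[1.0, 1.0]])
        with pytest.raises(ValueError, match="numerator"):
            log_ratio(table, {"zzz"}, {"f1"})

    def test_group_assessment(self):
        rng = np.random.default_rng(0)
        n = 20
        num = np.concatenate([rng.uniform(5, 9, n), rng.uniform(1, 2, n)])
        den = np.ones(2 * n)
        values = np.vstack([num, den])
        sample_ids = [f"s{j}" for j in range(2 * n)]
        table = FeatureTable(values, ["up", "ref"], sample_ids)
        records = [
            SampleRecord(s, "x", "R" if j < n else "NR") for j, s in enumerate(sample_ids)
        ]
        res = assess_log_ratio(table, {"up"}, {"ref"}, records)
        assert res.group_p_value < 0.001


class TestWilcoxon:
    def test_enumerated_example(self):
        # 2 of the 20 assignments of {1..6} into 3+3 are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5]) == 1.0

    def test_exact_matches_enumeration_small_n(self):
        rng = np.random.default_rng(1)
        for n_a in range(1, 6):
            for n_b in range(1, 11 - n_a):
                data = rng.permutation(np.arange(1.0, n_a + n_b + 1))
                a, b = data[:n_a], data[n_a:]
                assert wilcoxon_rank_sum(a, b, mode="exact") == pytest.approx(
                    exact_rank_sum_p(a, b)
                ), (n_a, n_b)

    def test_normal_close_to_exact_at_n10(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            p_exact = wilcoxon_rank_sum(a, b, mode="exact")
            p_normal = wilcoxon_rank_sum(a, b, mode="normal")
            assert abs(p_exact - p_normal) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), expected)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_bounds(self, p):
        q = benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)


class TestAitchison:
    def test_identity(self):
        assert aitchison_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_scale_invariance(self):
        assert aitchison_distance([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        assert aitchison_distance([2, 8], [8, 2]) == pytest.approx(2 * math.sqrt(2) * math.log(2))

    def test_zero_without_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            aitchison_distance([0, 1], [1, 1])

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.uniform(0.1, 10, 8)
            y = rng.uniform(0.1, 10, 8)
            clr_x = np.log(x) - np.log(x).mean()
            clr_y = np.log(y) - np.log(y).mean()
            expected = float(np.sqrt(((clr_x - clr_y) ** 2).sum()))
            assert aitchison_distance(x, y) == pytest.approx(expected)

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(5)
        table = FeatureTable(rng.integers(0, 20, (6, 4)).astype(float), list("abcdef"), list("wxyz"))
        mat = aitchison_distance_matrix(table, pseudocount=1.0)
        for i, si in enumerate(table.sample_ids):
            for j, sj in enumerate(table.sample_ids):
                expected = aitchison_distance(table.column(si), table.column(sj), pseudocount=1.0)
                assert mat[i, j] == pytest.approx(expected)


class TestBrayCurtis:
    def test_disjoint_is_one(self):
        assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_identity(self):
        assert bray_curtis([2, 3], [2, 3]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=10),
        st.data(),
    )
    def test_bounds(self, x, data):
        y = data.draw(
            st.lists(
                st.floats(min_value=0, max_value=100), min_size=len(x), max_size=len(x)
            )
        )
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0


class TestPermanova:
    def separated_toy(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        return d, ["a"] * 3 + ["b"] * 3

    def test_toy_exhaustive(self):
        d, labels = self.separated_toy()
        res = permanova(d, labels, exhaustive=True)
        assert res.p_value == pytest.approx(0.1)
        assert res.r_squared == pytest.approx(1.0)

    def test_exhaustive_matches_sampled_distribution(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        labels = ["a"] * 4 + ["b"] * 4
        exact = permanova(d, labels, exhaustive=True)
        sampled = permanova(d, labels, n_permutations=20000, seed=0)
        assert abs(exact.p_value - sampled.p_value) < 0.02

    def test_matches_skbio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d), grouping=labels, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_p_value_floor(self):
        d, labels = self.separated_toy()
        res = permanova(d, labels, n_permutations=100, seed=0)
        assert res.p_value >= 1.0 / 101
        assert 0.0 <= res.r_squared <= 1.0

    def test_singleton_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, ["a", "a", "b"])

    def test_asymmetric_matrix_rejected(self):
        d = np.zeros((4, 4))
        d[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            permanova(d, ["a", "a", "b", "b"])
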