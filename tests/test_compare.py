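"""Platform comparison: cosine identities, pruning rule, chi-square oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from vaxdiscourse.compare import (
    CategoryDistribution,
    anti_category_distributions,
    chi_square_homogeneity,
    cosine_similarity,
    pairwise_posthoc,
    prune_zero_expected,
    similarity_matrix,
)
from vaxdiscourse.corpus import ContingencyTable
from vaxdiscourse.errors import InsufficientDataError, ValidationError


def _table(data, platforms=None):
    platforms = platforms or [f"p{i}" for i in range(len(next(iter(data.values()))))]
    return ContingencyTable(
        pd.DataFrame.from_dict(data, orient="index", columns=platforms)
    )


def _dist(values, platform="p", cats=None):
    values = np.asarray(values, dtype=float)
    cats = cats or tuple(range(1, len(values) + 1))
    return CategoryDistribution(platform, tuple(cats), values)


class TestDistributions:
    def test_simple_normalization(self, codebook):
        data = {k: [0] for k in codebook.ids}
        data[1] = [2]
        data[2] = [2]
        dists = anti_category_distributions(_table(data, ["facebook"]), codebook)
        assert dists[0].freq[0] == 0.5 and dists[0].freq[1] == 0.5
        assert dists[0].freq.sum() == pytest.approx(1.0, abs=1e-12)

    def test_positive_category_excluded(self, codebook):
        data = {k: [1] for k in codebook.ids}
        dists = anti_category_distributions(_table(data, ["facebook"]), codebook)
        assert len(dists[0].freq) == 14
        assert 0 not in dists[0].categories

    def test_identical_counts_identical_vectors(self, table2_identical_table, codebook):
        dists = anti_category_distributions(table2_identical_table, codebook)
        for d in dists[1:]:
            assert np.allclose(d.freq, dists[0].freq, atol=1e-15)

    def test_published_marginal_fractions(self, table2_identical_table, codebook):
        """With every platform carrying the published marginal counts, each
        anti vector equals the marginal anti distribution (category 1 =
        156/729)."""
        dists = anti_category_distributions(table2_identical_table, codebook)
        assert dists[0].freq[0] == pytest.approx(156 / 729, abs=1e-12)

    def test_platform_without_anti_comments_named(self, codebook):
        data = {k: [0, 1] for k in codebook.ids}
        data[0] = [5, 5]
        for k in codebook.anti_ids:
            data[k] = [0, 1]
        with pytest.raises(ValidationError, match="pa"):
            anti_category_distributions(_table(data, ["pa", "pb"]), codebook)


class TestCosine:
    def test_self_similarity_is_one(self):
        d = _dist([0.2, 0.5, 0.3])
        assert cosine_similarity(d, d) == 1.0

    def test_disjoint_support_is_zero(self):
        assert cosine_similarity(_dist([1, 0, 0]), _dist([0, 1, 1])) == 0.0

    def test_half_overlap_derived_value(self):
        x = _dist([0.5, 0.5, 0.0])
        y = _dist([0.5, 0.0, 0.5])
        assert cosine_similarity(x, y) == pytest.approx(0.5, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            cosine_similarity(_dist([0, 0]), _dist([1, 0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cosine_similarity(_dist([1, 0]), _dist([1, 0, 0]))

    @given(
        st.lists(st.floats(0, 1e6), min_size=3, max_size=14),
        st.lists(st.floats(0, 1e6), min_size=3, max_size=14),
        st.floats(0.01, 100.0),
    )
    def test_bounds_symmetry_scale_invariance(self, xs, ys, scale):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]) + 1e-9, np.array(ys[:n]) + 1e-9
        a, b = _dist(x), _dist(y)
        s = cosine_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert cosine_similarity(b, a) == s
        assert cosine_similarity(_dist(scale * x), b) == pytest.approx(s, abs=1e-9)

    def test_raw_counts_equal_normalized(self, codebook):
        """Cosine on raw anti counts equals cosine on normalized frequencies."""
        rng = np.random.default_rng(3)
        raw = rng.integers(1, 50, size=(14, 2)).astype(float)
        a_raw, b_raw = _dist(raw[:, 0]), _dist(raw[:, 1])
        a_nrm = _dist(raw[:, 0] / raw[:, 0].sum())
        b_nrm = _dist(raw[:, 1] / raw[:, 1].sum())
        assert cosine_similarity(a_raw, b_raw) == pytest.approx(
            cosine_similarity(a_nrm, b_nrm), abs=1e-12
        )


class TestSimilarityMatrix:
    def test_two_identical_platforms(self):
        sm = similarity_matrix([_dist([1, 2], "a"), _dist([1, 2], "b")])
        assert np.allclose(sm.scores, 1.0)

    def test_four_platforms_shape_and_symmetry(self):
        rng = np.random.default_rng(0)
        dists = [_dist(rng.random(14) + 0.01, f"p{i}") for i in range(4)]
        sm = similarity_matrix(dists)
        assert sm.scores.shape == (4, 4)
        assert np.allclose(sm.scores, sm.scores.T)
        assert np.allclose(np.diag(sm.scores), 1.0)
        assert len(sm.off_diagonal_pairs()) == 6

    def test_single_platform_rejected(self):
        with pytest.raises(ValidationError):
            similarity_matrix([_dist([1, 2])])


class TestPruning:
    def test_zero_on_two_platforms_removed(self):
        table = _table({1: [0, 0, 8, 13], 2: [5, 5, 5, 5]})
        pruned, removed = prune_zero_expected(table)
        assert removed == [1]
        assert pruned.categories == (2,)

    def test_zero_on_one_platform_kept(self):
        table = _table({1: [0, 5, 8, 13], 2: [5, 5, 5, 5]})
        pruned, removed = prune_zero_expected(table)
        assert removed == []
        assert pruned.categories == (1, 2)

    def test_no_zeros_is_identity(self):
        table = _table({1: [1, 2], 2: [3, 4]})
        pruned, removed = prune_zero_expected(table)
        assert removed == []
        assert pruned.counts.equals(table.counts)

    def test_all_removed_raises(self):
        table = _table({1: [0, 0], 2: [0, 0]})
        with pytest.raises(InsufficientDataError):
            prune_zero_expected(table)


class TestChiSquare:
    def test_identical_distributions_zero_statistic(self):
        table = _table({1: [10, 20], 2: [20, 40], 3: [5, 10]})
        res = chi_square_homogeneity(table)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_2x2_hand_formula(self):
        """chi2 = n(ad - bc)^2 / (r1 r2 c1 c2), no continuity correction."""
        res = chi_square_homogeneity(_table({1: [10, 20], 2: [20, 10]}))
        hand = 60 * (10 * 10 - 20 * 20) ** 2 / (30 * 30 * 30 * 30)
        assert res.chi2 == pytest.approx(hand, abs=1e-9)
        assert res.chi2 == pytest.approx(6.6667, abs=1e-4)
        assert res.df == 1
        assert res.p == pytest.approx(chi2_dist.sf(hand, 1), abs=1e-12)
        assert res.p == pytest.approx(0.0098, abs=5e-4)

    def test_doubling_counts_doubles_statistic(self):
        t1 = _table({1: [10, 20], 2: [20, 10]})
        t2 = _table({1: [20, 40], 2: [40, 20]})
        r1, r2 = chi_square_homogeneity(t1), chi_square_homogeneity(t2)
        assert r2.chi2 == pytest.approx(2 * r1.chi2)
        assert r2.df == r1.df

    def test_df_formula(self):
        res = chi_square_homogeneity(
            _table({1: [5, 6, 7, 8], 2: [8, 7, 6, 5], 3: [4, 4, 4, 4]})
        )
        assert res.df == (3 - 1) * (4 - 1)

    def test_zero_expected_instructs_pruning(self):
        with pytest.raises(ValidationError, match="prune"):
            chi_square_homogeneity(_table({1: [0, 0], 2: [5, 5]}))


class TestPosthoc:
    def test_four_platforms_give_six_pairs(self):
        rng = np.random.default_rng(1)
        table = _table({k: list(rng.integers(5, 30, 4)) for k in range(1, 6)})
        results = pairwise_posthoc(table)
        assert len(results) == 6
        for r in results:
            assert r.p_adjusted >= r.p_raw
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_identical_pair_not_significant(self):
        table = _table({1: [10, 10, 30], 2: [20, 20, 5]})
        results = {r.pair: r for r in pairwise_posthoc(table)}
        r = results[("p0", "p1")]
        assert r.p_raw == pytest.approx(1.0)
        assert r.p_adjusted == pytest.approx(1.0)
        assert r.significant is False

    def test_bonferroni_arithmetic(self):
        # p_raw = 0.01 with m = 6 pairs -> p_adjusted = 0.06
        assert min(1.0, 6 * 0.01) == pytest.approx(0.06)
        rng = np.random.default_rng(2)
        table = _table({k: list(rng.integers(10, 40, 4)) for k in range(1, 5)})
        for r in pairwise_posthoc(table):
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_pairwise_pruning_local_to_pair(self):
        # category 1 is zero on p0 and p1 only: removed for that pair alone
        table = _table({1: [0, 0, 9, 9], 2: [5, 6, 7, 8], 3: [9, 8, 7, 6]})
        results = {r.pair: r for r in pairwise_posthoc(table)}
        assert results[("p0", "p1")].removed_categories == (1,)
        assert results[("p2", "p3")].removed_categories == ()
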