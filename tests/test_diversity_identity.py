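"""Bray-Curtis, alpha diversity, ROC calibration and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from metacrispr.asv_denoise import ASVTable
from metacrispr.diversity_identity import (
    binarize,
    bray_curtis,
    bonferroni,
    call_identity,
    group_distances,
    mann_whitney_exact,
    observed_otus,
    pairwise_distances,
    roc_curve,
    shannon,
    spearman_gated,
    zscore_standardize,
)
from metacrispr.io_core import SampleMetadata


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([3, 2, 1], [3, 2, 1]) == 0.0
        assert bray_curtis([3, 0, 0], [0, 2, 1]) == 1.0

    def test_hand_computed_example(self):
        assert bray_curtis([2, 1, 0], [1, 0, 1]) == pytest.approx(0.6)

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            u = rng.integers(0, 50, size=n).astype(float)
            v = rng.integers(0, 50, size=n).astype(float)
            if u.sum() + v.sum() == 0:
                continue
            assert bray_curtis(u, v) == pytest.approx(scipy_braycurtis(u, v), abs=1e-12)

    def test_symmetry_bounds_and_scale_covariance(self, rng):
        for _ in range(200):
            u = rng.integers(0, 20, size=10).astype(float)
            v = rng.integers(0, 20, size=10).astype(float)
            if u.sum() + v.sum() == 0:
                continue
            d = bray_curtis(u, v)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(v, u))
            assert bray_curtis(2 * u, 2 * v) == pytest.approx(d)
            perm = rng.permutation(10)
            assert bray_curtis(u[perm], v[perm]) == pytest.approx(d)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)),
            min_size=1,
            max_size=20,
        )
    )
    def test_metric_properties_hold_for_arbitrary_count_pairs(self, pairs):
        u = [a for a, _ in pairs]
        v = [b for _, b in pairs]
        if sum(u) + sum(v) == 0:
            return
        d = bray_curtis(u, v)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(v, u))
        if u == v:
            assert d == 0.0

    def test_double_empty_defined_as_one(self):
        assert bray_curtis([0, 0], [0, 0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 2], [1, 2, 3])


class TestAlphaDiversity:
    def test_observed_otus(self):
        assert observed_otus([5, 0, 2]) == 2
        assert observed_otus([0, 0]) == 0
        assert observed_otus([1, 1, 1, 1]) == 4

    def test_shannon_base2(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(2.0)
        assert shannon([7]) == pytest.approx(0.0)
        assert shannon([3, 1]) == pytest.approx(0.8112781, abs=1e-6)

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestPairwiseAndIdentity:
    def test_identical_samples_have_zero_distance(self):
        table = ASVTable.from_counts({"a": {"AAAA": 5, "CCCC": 3}, "b": {"AAAA": 5, "CCCC": 3}})
        dm = pairwise_distances(table)
        assert dm["a", "b"] == 0.0

    def test_all_zero_sample_row_of_ones(self):
        table = ASVTable.from_counts({"a": {"AAAA": 5}, "b": {}, "c": {"AAAA": 2}})
        dm = pairwise_distances(table)
        assert dm["b", "a"] == 1.0 and dm["b", "c"] == 1.0

    @pytest.mark.parametrize(
        "distance,call",
        [(0.19, "same_source"), (0.86, "different_source"), (0.8, "different_source")],
    )
    def test_strict_threshold_rule(self, distance, call):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0.0, distance], [distance, 0.0]]), ids=["q", "r"])
        res = call_identity(dm, "q", "r")
        assert res.call == call
        assert res.threshold == 0.8

    def test_missing_sample_rejected(self):
        table = ASVTable.from_counts({"a": {"AAAA": 5}, "b": {"AAAA": 2}})
        with pytest.raises(KeyError):
            call_identity(table, "a", "zzz")


def auc_oracle(pos, neg):
    """Brute-force pairwise comparison probability with half-credit ties."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        d = [0.1, 0.2, 0.9, 1.0]
        y = [True, True, False, False]
        res = roc_curve(d, y)
        assert res.auc == pytest.approx(1.0)
        assert res.best_sensitivity == 1.0 and res.best_specificity == 1.0
        assert 0.2 < res.best_threshold <= 0.9

    def test_identical_distributions_auc_half(self):
        d = [0.3, 0.5, 0.7, 0.3, 0.5, 0.7]
        y = [True, True, True, False, False, False]
        assert roc_curve(d, y).auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle_exhaustively(self, rng):
        for _ in range(200):
            n_pos = int(rng.integers(1, 9))
            n_neg = int(rng.integers(1, 9))
            # coarse grid provokes ties within and across classes
            pos = rng.choice([0.1, 0.2, 0.5, 0.8, 0.9], size=n_pos)
            neg = rng.choice([0.1, 0.2, 0.5, 0.8, 0.9], size=n_neg)
            d = np.concatenate([pos, neg])
            y = np.array([True] * n_pos + [False] * n_neg)
            res = roc_curve(d, y)
            assert res.auc == pytest.approx(auc_oracle(pos, neg), abs=1e-12)
            # independent cross-check: sklearn on the negated distances
            assert res.auc == pytest.approx(roc_auc_score(y, -d), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [True, True])

    def test_best_threshold_maximizes_youden(self):
        d = [0.1, 0.4, 0.35, 0.9]
        y = [True, True, False, False]
        res = roc_curve(d, y)
        youden = [s + p for s, p in zip(res.sensitivity, res.specificity)]
        best = max(youden)
        idx = res.thresholds.index(res.best_threshold)
        assert youden[idx] == best


class TestGroupStats:
    def _meta(self):
        meta = []
        for ind, house in [("A", "H1"), ("B", "H1"), ("C", "H2")]:
            meta.append(SampleMetadata(f"skin_{ind}", ind, house, "skin"))
            meta.append(SampleMetadata(f"sal_{ind}", ind, house, "saliva"))
        return meta

    def test_partition_and_tests(self):
        meta = self._meta()
        ids = [m.sample_id for m in meta]
        n = len(ids)
        rng = np.random.default_rng(5)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = rng.uniform(0.1, 1.0)
        from skbio import DistanceMatrix

        dm = DistanceMatrix(mat, ids=ids)
        res = group_distances(dm, meta)
        assert len(res.groups["within_individual"]) == 3
        assert len(res.groups["within_household"]) == 2  # A-B skin x saliva
        assert len(res.groups["between_household"]) == 4
        assert res.kw_p is not None
        assert all(0 <= p <= 1 for p in res.pairwise_adjusted_p.values())

    def test_identical_values_not_significant(self):
        meta = self._meta()
        ids = [m.sample_id for m in meta]
        mat = np.ones((len(ids), len(ids))) * 0.5
        np.fill_diagonal(mat, 0.0)
        from skbio import DistanceMatrix

        res = group_distances(DistanceMatrix(mat, ids=ids), meta)
        assert res.kw_p == pytest.approx(1.0)
        assert all(p == 1.0 for p in res.pairwise_adjusted_p.values())

    def test_empty_group_skips_kw(self):
        meta = [
            SampleMetadata("skin_A", "A", "H1", "skin"),
            SampleMetadata("sal_A", "A", "H1", "saliva"),
        ]
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ids=["skin_A", "sal_A"])
        res = group_distances(dm, meta)
        assert res.kw_p is None and "skipped" in res.diagnostics

    def test_exact_mwu_matches_full_enumeration(self):
        x = [0.1, 0.2]
        y = [0.9, 1.0]
        # complete separation in 2x2: exact two-sided p = 2/C(4,2) = 1/3
        assert mann_whitney_exact(x, y) == pytest.approx(2 / 6)
        # scipy exact agrees where there are no ties
        p_scipy = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mann_whitney_exact(x, y) == pytest.approx(p_scipy)

    def test_bonferroni_multiply_and_cap(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 3) == 1.0


class TestSpearmanAndTransforms:
    def test_monotone_sequences(self):
        up = spearman_gated([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        assert up.reported and up.r == pytest.approx(1.0)
        down = spearman_gated([1, 2, 3, 4, 5, 6], [60, 50, 40, 30, 20, 10])
        assert down.reported and down.r == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        res = spearman_gated([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        # n=5 with r=0.8 is not significant at 0.05: gated out
        assert not res.reported and res.p_value >= 0.05

    def test_constant_vector_suppressed(self):
        res = spearman_gated([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.suppressed and res.r is None

    def test_zscore_population_convention(self, rng):
        x = rng.normal(3.0, 2.0, size=40)
        z = zscore_standardize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)
        assert (zscore_standardize(np.ones(5)) == 0).all()

    def test_binarize_idempotent(self, rng):
        x = rng.integers(0, 5, size=30)
        b = binarize(x)
        assert set(np.unique(b)) <= {0, 1}
        assert (binarize(b) == b).all()
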