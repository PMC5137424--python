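"""Element scoring statistics: window-maximum score, normalization,
replicate concordance, relative differences, filtering, classification
and rank-sum comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from occupre.intervals import GenomicInterval
from occupre.scoring import (
    classify_pre,
    compare_distributions,
    filter_pres,
    normalize_score,
    relative_difference,
    replicate_concordance,
    top_window_mean,
    weak_signal_threshold,
)


class TestTopWindowMean:
    @pytest.mark.parametrize(
        "segment, window, expected",
        [
            (np.full(1000, 5.0), 6, 5.0),
            (list(range(10)), 6, 6.5),  # windows 0-4: best is [4..9] -> 39/6
            ([0] * 50 + [12] + [0] * 50, 6, 2.0),
            ([3.0, 1.0, 4.0], 1, 4.0),
        ],
    )
    def test_examples(self, segment, window, expected):
        assert top_window_mean(segment, window) == pytest.approx(expected)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="length 3 shorter than window 6"):
            top_window_mean([1, 2, 3], 6)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 100), min_size=6, max_size=60),
        st.integers(1, 6),
    )
    def test_matches_exhaustive_enumeration(self, seg, window):
        expected = max(
            sum(seg[i : i + window]) / window
            for i in range(len(seg) - window + 1)
        )
        assert top_window_mean(seg, window) == pytest.approx(expected)


class TestNormalize:
    def test_identity_at_scale(self):
        assert normalize_score(10, 1e6) == 10

    def test_linearity(self):
        assert normalize_score(10, 2e6) == 5

    def test_track_doubling_invariance(self):
        """Doubling every base (raw and depth) leaves the score unchanged."""
        seg = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 1.0, 0.0])
        raw = top_window_mean(seg, 3)
        raw2 = top_window_mean(2 * seg, 3)
        assert normalize_score(raw, seg.sum()) == pytest.approx(
            normalize_score(raw2, 2 * seg.sum())
        )

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="total_depth"):
            normalize_score(10, 0)


class TestConcordance:
    def test_perfect_linear(self):
        a = np.array([1.0, 2, 3, 5, 8])
        assert replicate_concordance(a, 2 * a) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = np.array([1.0, 2, 3, 5, 8])
        assert replicate_concordance(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_ten_elements(self):
        # textbook formula r = cov(x, y) / (sd_x sd_y) computed directly
        x = np.array([2.0, 4, 5, 5, 6, 7, 8, 9, 10, 12])
        y = np.array([1.0, 3, 6, 4, 7, 6, 9, 8, 12, 11])
        expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert replicate_concordance(x, y) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9416, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            replicate_concordance([1, 1, 1], [1, 2, 3])


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "m, c, expected",
        [
            (3.0, 3.0, 0.0),
            (0.0, 5.0, -2.0),
            (0.23, 1.0, 2 * (0.23 - 1) / 1.23),  # ~ -1.252
        ],
    )
    def test_examples(self, m, c, expected):
        assert relative_difference(m, c) == pytest.approx(expected, abs=1e-9)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="both means are zero"):
            relative_difference(0, 0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_antisymmetry_and_range(self, m, c):
        rd = relative_difference(m, c)
        assert rd == pytest.approx(-relative_difference(c, m))
        assert -2 < rd < 2

    def test_strictly_monotone_in_mutant_mean(self):
        c = 3.0
        rds = [relative_difference(m, c) for m in np.linspace(0.01, 50, 200)]
        assert np.all(np.diff(rds) > 0)


class TestClassify:
    @pytest.mark.parametrize(
        "rd, expected",
        [
            (-0.15, "independent"),
            (-1.2, "dependent"),
            (-0.7, "intermediate"),
            (-1.0, "intermediate"),  # boundaries are not dependent/independent
            (-0.5, "intermediate"),
        ],
    )
    def test_thresholds(self, rd, expected):
        assert classify_pre(rd) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            classify_pre(float("nan"))


class TestFilter:
    @staticmethod
    def _catalog(n, width=100):
        return [
            GenomicInterval("c", i * 1000, i * 1000 + width) for i in range(n)
        ]

    def test_deletion_overlap_removed(self):
        catalog = self._catalog(3)
        exclusion = [GenomicInterval("c", 950, 1200)]  # overlaps element 1
        kept, reasons = filter_pres(catalog, [50, 60, 70], exclusion,
                                    weak_fraction=0.0)
        assert kept == [0, 2]
        assert reasons == {1: "deletion_overlap"}

    def test_dynamic_range_rule(self):
        scores = list(range(0, 101, 10))  # 0, 10, ..., 100 -> threshold 30
        catalog = self._catalog(11)
        kept, reasons = filter_pres(catalog, scores, [])
        assert kept == [3, 4, 5, 6, 7, 8, 9, 10]
        assert set(reasons.values()) == {"weak_signal"}

    def test_equal_scores_disable_weak_rule(self):
        catalog = self._catalog(4)
        with pytest.warns(UserWarning, match="dynamic range is zero"):
            kept, reasons = filter_pres(catalog, [5, 5, 5, 5], [])
        assert kept == [0, 1, 2, 3] and reasons == {}

    def test_quantile_mode(self):
        scores = np.array([0.0, 1, 2, 3, 100])
        assert weak_signal_threshold(scores, 0.30, "quantile") == pytest.approx(
            np.quantile(scores, 0.3)
        )

    def test_everything_filtered_is_an_error(self):
        catalog = self._catalog(2)
        exclusion = [GenomicInterval("c", 0, 5000)]
        with pytest.raises(ValueError, match="no elements left"):
            filter_pres(catalog, [1, 2], exclusion)


def _exact_ranksum_p(a, b):
    """Exhaustive permutation null of the rank-sum statistic (two-sided)."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties in the fixtures
    na = len(a)
    obs = ranks[:na].sum()
    null = [
        sum(comb) for comb in itertools.combinations(ranks, na)
    ]
    null = np.array(null)
    mu = null.mean()
    p = np.mean(np.abs(null - mu) >= abs(obs - mu) - 1e-12)
    return p


class TestCompareDistributions:
    def test_identical_vectors_p_one(self):
        a = [1.0, 2, 3, 4, 5]
        res = compare_distributions(a, a)
        assert res["pvalue"] > 0.9

    def test_small_sample_matches_exact_enumeration(self):
        a, b = [1.0, 2, 3], [11.0, 12, 13]
        res = compare_distributions(a, b)
        assert res["pvalue"] == pytest.approx(_exact_ranksum_p(a, b))
        assert res["pvalue"] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 6))
        b = rng.normal(1.0, size=rng.integers(3, 6))
        res = compare_distributions(a, b)
        assert res["pvalue"] == pytest.approx(_exact_ranksum_p(a, b))

    def test_shifted_gaussians_significant(self):
        rng = np.random.default_rng(135)
        a = rng.normal(0, 1, 135)
        b = rng.normal(1, 1, 135)
        res = compare_distributions(a, b)
        assert res["pvalue"] < 1e-6
        assert res["median_a"] < res["median_b"]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_distributions([1, 2], [3, 4, 5])
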