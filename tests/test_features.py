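"""Windowed predictors against independent oracles: exhaustive sample-entropy
enumeration, direct Pearson arithmetic, a second DFA implementation, and
order-statistic medians."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from respwatch.features import (
    FEATURE_NAMES,
    FeatureParams,
    cosen,
    dfa_variance_slope,
    feature_medians,
    impute_missing,
    iter_windows,
    sample_entropy,
    sdnn,
    window_cross_correlations,
    window_vitals_stats,
)

# ---------------------------------------------------------------------------
# oracles


def sampen_bruteforce(x, m, r):
    """Exhaustive O(N^2) template-pair enumeration.

    A runs over all start pairs of length-(m+1) templates, B over all start
    pairs of length-m templates (each count over the maximal valid index
    range for its own template length)."""
    x = np.asarray(x, float)
    n = len(x)

    def count(length):
        starts = range(n - length + 1)
        c = 0
        for i in starts:
            for j in starts:
                if i < j and max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    a = count(m + 1)
    b = count(m)
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def dfa_textbook_alpha(x, scales):
    """Classic DFA: log fluctuation (not variance) versus log scale."""
    y = np.cumsum(np.asarray(x, float) - np.mean(x))
    f = []
    for n in scales:
        nbox = len(y) // n
        res = []
        for seg in (y[: nbox * n], y[len(y) - nbox * n :]):
            for box in seg.reshape(nbox, n):
                t = np.arange(n)
                a, b = np.polyfit(t, box, 1)
                res.append(np.mean((box - (a * t + b)) ** 2))
        f.append(np.sqrt(np.mean(res)))
    return np.polyfit(np.log(scales), np.log(f), 1)[0]


# ---------------------------------------------------------------------------


class TestIterWindows:
    def test_one_hour_span_gives_three_windows(self):
        assert iter_windows(0, 60) == [(0.0, 30.0), (15.0, 45.0), (30.0, 60.0)]

    def test_span_shorter_than_window_is_empty(self):
        assert iter_windows(0, 29) == []

    def test_24h_span_window_count_closed_form(self):
        # ends at 30, 45, ..., 1440: (1440 - 30)/15 + 1 windows
        wins = iter_windows(0, 1440)
        assert len(wins) == (1440 - 30) // 15 + 1 == 95
        ends = np.array([e for _, e in wins])
        np.testing.assert_allclose(np.diff(ends), 15.0)


class TestVitalsStats:
    def test_constant_window(self):
        mean, sd = window_vitals_stats(np.full(30, 80.0))
        assert (mean, sd) == (80.0, 0.0)

    def test_two_point_sd(self):
        mean, sd = window_vitals_stats(np.array([70.0, 90.0]), min_samples=2)
        assert mean == 80.0
        assert sd == pytest.approx(20.0 / np.sqrt(2), abs=1e-9)

    def test_gaussian_recovery(self):
        x = np.random.default_rng(0).normal(80, 5, 5000)
        mean, sd = window_vitals_stats(x)
        assert mean == pytest.approx(80, abs=0.3)
        assert sd == pytest.approx(5, abs=0.2)

    def test_too_few_samples_missing(self):
        mean, sd = window_vitals_stats(np.array([80.0] * 5), min_samples=10)
        assert np.isnan(mean) and np.isnan(sd)


class TestCrossCorrelation:
    def test_self_correlation_is_one(self):
        x = np.arange(30.0)
        assert window_cross_correlations(x, x) == pytest.approx(1.0)

    def test_anticorrelated_is_minus_one(self):
        x = np.arange(30.0)
        assert window_cross_correlations(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        want = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert window_cross_correlations(x, y) == pytest.approx(want, abs=1e-12)

    def test_pairwise_complete_with_missing(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + 1
        x[::5] = np.nan
        assert window_cross_correlations(x, y) == pytest.approx(1.0)

    def test_zero_variance_is_missing(self):
        assert np.isnan(window_cross_correlations(np.full(30, 1.0), np.arange(30.0)))

    @given(st.integers(0, 10**6))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=15) * r.uniform(0.1, 100)
        y = x * r.uniform(-2, 2) + r.normal(size=15)
        v = window_cross_correlations(x, y)
        assert np.isnan(v) or -1.0 <= v <= 1.0


class TestSampleEntropy:
    def test_constant_series_matches_exhaustive_count(self):
        # edge templates enter B only, so A/B < 1 and SampEn > 0
        x = np.full(20, 800.0)
        want = sampen_bruteforce(x, 1, 30.0)
        assert want > 0
        assert sample_entropy(x, 1, 30.0) == pytest.approx(want, abs=1e-12)

    def test_alternating_series_equals_exhaustive_count(self):
        # repeated (1,100) templates match each other: A=2, B=4
        x = [1.0, 100.0, 1.0, 100.0, 1.0]
        assert sampen_bruteforce(x, 1, 1.0) == pytest.approx(np.log(2.0))
        assert sample_entropy(x, m=1, r=1.0) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_series_without_length2_matches_is_missing(self):
        # one length-1 match (0, 0.5) but its successors differ: A=0
        x = [0.0, 0.5, 100.0, 300.0, 600.0]
        assert np.isnan(sampen_bruteforce(x, 1, 1.0))
        assert np.isnan(sample_entropy(x, m=1, r=1.0))

    def test_too_short_series_is_missing(self):
        assert np.isnan(sample_entropy([1.0, 2.0], m=1, r=1.0))

    @pytest.mark.parametrize("m", [1, 2])
    @pytest.mark.parametrize("n", [20, 50, 200])
    def test_equals_bruteforce_oracle_exactly(self, m, n):
        rng = np.random.default_rng(n * 10 + m)
        x = rng.normal(800, 50, n)
        want = sampen_bruteforce(x, m, 0.2 * np.std(x))
        got = sample_entropy(x, m, 0.2 * np.std(x))
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    @given(st.integers(0, 10**6))
    def test_property_equals_oracle_on_random_series(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 80))
        x = r.normal(0, 1, n)
        tol = 0.25
        want = sampen_bruteforce(x, 1, tol)
        got = sample_entropy(x, 1, tol)
        assert (np.isnan(want) and np.isnan(got)) or got == pytest.approx(
            want, abs=1e-12
        )


class TestCosen:
    def test_direct_formula_arithmetic(self):
        # with SampEn = 0 the value reduces to ln(2r) - ln(mean RR)
        x = np.full(50, 1000.0)
        se = sample_entropy(x, 1, 30.0)
        expected = se + np.log(60.0) - np.log(1000.0)
        assert cosen(x, 1, 30.0) == pytest.approx(expected, abs=1e-12)
        assert np.log(60.0) - np.log(1000.0) == pytest.approx(-2.813, abs=1e-3)

    def test_doubling_r_adds_ln2_minus_sampen_change(self, rng):
        x = rng.normal(800, 60, 300)
        d = cosen(x, 1, 60.0) - cosen(x, 1, 30.0)
        want = np.log(2) + sample_entropy(x, 1, 60.0) - sample_entropy(x, 1, 30.0)
        assert d == pytest.approx(want, abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.normal(800, 60, 400)
        a = cosen(x, 1, 30.0)
        b = cosen(2 * x, 1, 60.0)
        assert b == pytest.approx(a, abs=1e-9)


class TestDFA:
    def test_constant_series_missing(self):
        assert np.isnan(dfa_variance_slope(np.full(300, 800.0)))

    def test_white_noise_slope_near_one(self):
        rng = np.random.default_rng(2)
        slopes = [
            dfa_variance_slope(rng.normal(800, 50, 2000)) for _ in range(30)
        ]
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.1)

    def test_integrated_noise_slope_above_1p5(self):
        rng = np.random.default_rng(3)
        slopes = [
            dfa_variance_slope(np.cumsum(rng.normal(0, 1, 2000))) for _ in range(10)
        ]
        assert np.mean(slopes) > 1.5

    def test_equals_textbook_implementation_doubled(self, rng):
        x = rng.normal(0, 1, 400)
        scales = (4, 8, 16, 32)
        alpha = dfa_textbook_alpha(x, scales)
        assert dfa_variance_slope(x, scales) == pytest.approx(2 * alpha, abs=1e-9)
        assert dfa_variance_slope(x, scales, use_squared=False) == pytest.approx(
            alpha, abs=1e-9
        )

    def test_too_short_missing(self):
        assert np.isnan(dfa_variance_slope(np.zeros(100), scales=(4, 8, 64)))


class TestSDNN:
    def test_constant_zero(self):
        assert sdnn(np.full(200, 1000.0)) == 0.0

    def test_two_point(self):
        assert sdnn([900.0, 1100.0], min_beats=2) == pytest.approx(
            200.0 / np.sqrt(2), abs=1e-9
        )

    def test_gaussian_recovery(self, rng):
        assert sdnn(rng.normal(1000, 50, 4000)) == pytest.approx(50, rel=0.05)

    def test_too_few_beats_missing(self):
        assert np.isnan(sdnn([1000.0] * 3, min_beats=10))


class TestImputation:
    def make_table(self):
        df = pd.DataFrame(
            {
                "admission_id": ["a", "a", "b"],
                "window_end_min": [30.0, 45.0, 30.0],
                **{f: [1.0, np.nan, 3.0] for f in FEATURE_NAMES},
            }
        )
        return df

    def test_nothing_missing_is_identity(self):
        df = self.make_table().fillna(2.0)
        med = feature_medians(df)
        out = impute_missing(df, med)
        for f in FEATURE_NAMES:
            np.testing.assert_array_equal(out[f], df[f])
            assert not out[f"{f}_imputed"].any()

    def test_all_missing_row_becomes_medians_row(self):
        df = self.make_table()
        med = feature_medians(df)
        out = impute_missing(df, med)
        for f in FEATURE_NAMES:
            assert out.loc[1, f] == med[f]
            assert out.loc[1, f"{f}_imputed"]

    def test_median_matches_sort_based_oracle(self, rng):
        df = self.make_table()
        vals = rng.normal(size=11)
        df = pd.concat([df] * 4, ignore_index=True).iloc[:11].copy()
        df["cosen"] = vals
        med = feature_medians(df)
        assert med["cosen"] == np.sort(vals)[5]  # middle order statistic

    def test_unknown_feature_name_rejected(self):
        df = self.make_table()
        med = feature_medians(df)
        med["not_a_feature"] = 1.0
        with pytest.raises(KeyError, match="not_a_feature"):
            impute_missing(df, med)

    def test_missing_median_rejected(self):
        df = self.make_table()
        med = feature_medians(df).drop("cosen")
        with pytest.raises(KeyError, match="cosen"):
            impute_missing(df, med)
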