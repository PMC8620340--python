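"""Trend-screening tests: brute-force oracles for the Mann-Kendall statistic
and Sen slope, rank arithmetic for Kruskal-Wallis, and weighted-least-squares
oracles (plus a statsmodels cross-check) for loess."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from riverwqi import (
    TrendError,
    kruskal_wallis,
    loess_fit,
    mann_kendall,
    sen_slope,
)


def brute_s(x):
    return sum(
        np.sign(x[j] - x[i])
        for i in range(len(x))
        for j in range(i + 1, len(x))
    )


def brute_sen(x):
    return np.median(
        [
            (x[j] - x[i]) / (j - i)
            for i in range(len(x))
            for j in range(i + 1, len(x))
        ]
    )


class TestMannKendall:
    def test_monotone_series(self):
        res = mann_kendall([1, 2, 3, 4, 5])
        assert res.S == 10  # all 10 pairs increasing
        assert res.decision == "increasing"
        assert res.sen_slope == 1.0

    def test_constant_series_no_trend(self):
        res = mann_kendall([3.2] * 6)
        assert res.S == 0
        assert res.decision == "no_trend"
        assert res.sen_slope is None  # dash convention

    def test_tie_handling(self):
        res = mann_kendall([3, 1, 2, 2])
        # pairwise signs: -1 -1 -1 +1 +1 0 -> S = -1
        assert res.S == brute_s([3, 1, 2, 2]) == -1
        # tie correction: one group of 2 ties
        n = 4
        expected_var = (n * (n - 1) * (2 * n + 5) - 2 * 1 * 9) / 18
        assert res.variance_S == pytest.approx(expected_var)

    def test_too_short_rejected(self):
        with pytest.raises(TrendError):
            mann_kendall([1, 2, 3])

    def test_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 21)
            x = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
            res = mann_kendall(x, force_sen=True)
            assert res.S == brute_s(x)
            assert res.sen_slope == pytest.approx(brute_sen(x))

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, values):
        x = np.asarray(values, dtype=float)
        a = mann_kendall(x)
        b = mann_kendall(np.exp(x / 50.0))  # strictly increasing transform
        assert a.S == b.S and a.decision == b.decision

    def test_exact_small_n_matches_normal_direction(self):
        res = mann_kendall([1, 2, 3, 4, 5, 6], exact=True)
        assert res.decision == "increasing"
        # exact p for the perfectly ordered sequence: 2/6! * 1... two-sided
        assert res.p_value == pytest.approx(2 / 720, rel=1e-9)

    def test_missing_values_removed_pairwise(self):
        res = mann_kendall([1, np.nan, 2, 3, np.nan, 4, 5])
        assert res.n == 5 and res.S == 10


class TestSenSlope:
    def test_pairwise_median_example(self):
        # six pairwise slopes {2, 0.5, 1, -1, 0.5, 2} -> median 0.75
        assert sen_slope([1, 3, 2, 4]) == pytest.approx(0.75)

    def test_exact_linear_recovers_slope(self):
        t = np.arange(10)
        assert sen_slope(3.5 * t - 2) == pytest.approx(3.5)

    def test_constant_series(self):
        assert sen_slope([2, 2, 2, 2]) == 0.0

    def test_missing_values_widen_denominator(self):
        # indices 0 and 2 remain: slope (x2 - x0) / 2
        assert sen_slope([1.0, np.nan, 5.0]) == pytest.approx(2.0)

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=12),
        st.floats(-5, 5),
        st.floats(0.1, 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_equivariance(self, values, shift_rate, scale):
        x = np.asarray(values)
        t = np.arange(len(x))
        base = sen_slope(x)
        assert sen_slope(x + shift_rate * t) == pytest.approx(
            base + shift_rate, abs=1e-6
        )
        assert sen_slope(scale * x) == pytest.approx(scale * base, abs=1e-6)


class TestKruskalWallis:
    def test_hand_rank_oracle(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        # ranks 1..6, R1 = 6, R2 = 15: H = 12/42 * (12 + 75) - 21
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(h, 1))

    def test_identical_groups_give_zero(self):
        h, _ = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0

    def test_all_missing_group_dropped(self):
        with pytest.warns(UserWarning, match="all-missing"):
            h, _ = kruskal_wallis([[1, 2, 3], [np.nan] * 3, [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_fewer_than_two_groups_error(self):
        with pytest.raises(TrendError):
            kruskal_wallis([[1, 2, 3, 4, 5]])

    def test_invariant_under_common_monotone_transform(self):
        groups = [[1.0, 3.0, 7.0], [2.0, 8.0, 9.0], [4.0, 5.0, 6.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in map(np.asarray, groups)])
        assert h1 == pytest.approx(h2)


class TestLoess:
    def test_polynomial_reproduction(self):
        x = np.linspace(0, 10, 15)
        for degree in (1, 2):
            y = 1 + 2 * x + (0.5 * x**2 if degree == 2 else 0)
            fit = loess_fit(x, y, span_alpha=1.0, degree=degree)
            np.testing.assert_allclose(fit.fitted, y, atol=1e-8)

    def test_constant_data_any_span(self):
        x = np.arange(12.0)
        for span in (0.3, 0.5, 1.0):
            fit = loess_fit(x, np.full(12, 7.0), span, degree=1)
            np.testing.assert_allclose(fit.fitted, 7.0)

    def test_brute_force_wls_oracle_at_one_target(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 10, 20))
        y = np.sin(x) + rng.normal(0, 0.2, 20)
        span, degree, t = 0.4, 2, 7
        fit = loess_fit(x, y, span, degree)
        # independent normal-equations solve at target t
        q = int(np.ceil(span * len(x)))
        d = np.abs(x - x[t])
        nn = np.argsort(d, kind="stable")[:q]
        w = np.clip(1 - (d[nn] / d[nn].max()) ** 3, 0, None) ** 3
        X = np.vander(x[nn] - x[t], degree + 1, increasing=True)
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y[nn]))
        assert fit.fitted[t] == pytest.approx(beta[0], abs=1e-8)

    def test_matches_statsmodels_lowess_degree1(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 20))
        y = np.sin(x) + rng.normal(0, 0.1, 20)
        ours = loess_fit(x, y, span_alpha=0.5, degree=1).fitted
        ref = lowess(y, x, frac=0.5, it=0, return_sorted=False)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_span_too_small_rejected(self):
        with pytest.raises(TrendError, match="neighbours"):
            loess_fit(np.arange(10.0), np.arange(10.0), 0.1, degree=2)
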