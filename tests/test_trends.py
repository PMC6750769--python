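import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cfdattain import (
    classify_significance,
    generate_deficit_series,
    hamed_rao_factor,
    mk_s,
    modified_mk_test,
    pettitt_test,
    sen_slope,
    tie_variance,
)
from cfdattain.errors import InsufficientDataError, InvalidInputError


# ---------------------------------------------------------------- oracles
def brute_s(x):
    return sum(
        np.sign(x[j] - x[i]) for i, j in itertools.combinations(range(len(x)), 2)
    )


def brute_sen(x, t):
    slopes = [
        (x[j] - x[i]) / (t[j] - t[i])
        for i, j in itertools.combinations(range(len(x)), 2)
    ]
    return float(np.median(slopes))


def brute_pettitt_k(x):
    n = len(x)
    best_k, best_tau = -1, None
    for t in range(1, n):
        u = sum(
            np.sign(x[j] - x[i]) for i in range(t) for j in range(t, n)
        )
        if abs(u) > best_k:
            best_k, best_tau = abs(u), t
    return int(best_k), best_tau


FIXTURE_SERIES = [
    [3.0, 1.0, 2.0, 4.0],
    [0.0, 0.0, 1.0, 1.0, 0.5],
    [-5.0, -4.0, -3.0, -2.0, -1.0],
    [-1.0, -2.0, -3.0, -4.0, -5.0, -6.0],
    [2.0, 2.0, 2.0, 2.0],
    [-50.0, -20.0, -80.0, -10.0, -60.0, -30.0, -40.0],
    [1.0, 5.0, 2.0, 8.0, 3.0, 9.0, 4.0],
]


class TestMkS:
    def test_strictly_increasing_all_concordant(self):
        assert mk_s([1, 2, 3, 4, 5]) == 10

    def test_constant_is_zero(self):
        assert mk_s([2.0] * 6) == 0

    def test_hand_example(self):
        # brute force over all 6 pairs of (3, 1, 2, 4)
        assert mk_s([3, 1, 2, 4]) == 2 == brute_s([3, 1, 2, 4])

    @pytest.mark.parametrize("series", FIXTURE_SERIES)
    def test_matches_pair_enumeration(self, series):
        assert mk_s(series) == brute_s(series)

    def test_reversal_negates(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            assert mk_s(x[::-1]) == -mk_s(x)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            mk_s([1.0])


class TestTieVariance:
    def test_distinct_closed_form(self):
        # n=10 distinct: 10*9*25/18 = 125
        assert tie_variance(np.arange(10.0)) == pytest.approx(125.0)

    def test_all_tied_degenerates_to_zero(self):
        assert tie_variance([7.0] * 8) == 0.0

    def test_one_tied_pair_n5(self):
        # untied 5*4*15/18 minus 2*1*9/18 = 16.666... - 1
        assert tie_variance([1.0, 2.0, 2.0, 3.0, 4.0]) == pytest.approx(
            5 * 4 * 15 / 18 - 1.0
        )

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            tie_variance([1.0, 2.0])


class TestSenSlope:
    def test_exact_linear(self):
        t = np.arange(8.0)
        assert sen_slope(0.5 * t, t) == pytest.approx(0.5)

    def test_constant_is_zero(self):
        assert sen_slope([3.0] * 5) == 0.0

    def test_hand_example_enumeration(self):
        x, t = [0.0, 3.0, 1.0, 6.0], [1.0, 2.0, 3.0, 4.0]
        assert sen_slope(x, t) == pytest.approx(brute_sen(x, t))

    @pytest.mark.parametrize("series", FIXTURE_SERIES)
    def test_matches_pairwise_enumeration(self, series):
        t = list(range(len(series)))
        assert sen_slope(series, t) == pytest.approx(brute_sen(series, t))

    def test_agrees_with_theilslopes(self, rng):
        for _ in range(10):
            x = rng.normal(size=15)
            assert sen_slope(x) == pytest.approx(
                stats.theilslopes(x, np.arange(15.0)).slope
            )

    def test_nonincreasing_time_rejected(self):
        with pytest.raises(InvalidInputError):
            sen_slope([1.0, 2.0], [1.0, 1.0])


class TestHamedRaoFactor:
    def test_pure_trend_has_unit_factor(self):
        # Sen-detrending a perfect line leaves total ties: all rho_k = 0
        assert hamed_rao_factor(np.arange(10.0)) == 1.0

    def test_short_series_degrades_to_one(self):
        assert hamed_rao_factor([1.0, 2.0, 0.0]) == 1.0

    def test_positive_autocorrelation_inflates_in_expectation(self):
        # AR(1), phi = 0.8, n = 30: the mean factor over seeds must exceed 1
        factors = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            x = np.empty(30)
            x[0] = rng.normal()
            for i in range(1, 30):
                x[i] = 0.8 * x[i - 1] + rng.normal() * 0.6
            factors.append(hamed_rao_factor(x))
        assert np.mean(factors) > 1.0

    def test_all_lags_policy_matches_independent_formula(self, rng):
        """Re-derive the factor from scratch: Sen-detrend, rank, autocorrelate."""
        for _ in range(10):
            x = rng.normal(size=20).cumsum()  # strongly autocorrelated
            n = len(x)
            t = np.arange(n, dtype=float)
            detrended = x - sen_slope(x, t) * t
            ranks = stats.rankdata(detrended)
            r = ranks - ranks.mean()
            total = 0.0
            for k in range(1, n - 2):
                rho = np.sum(r[:-k] * r[k:]) / np.sum(r * r)
                total += (n - k) * (n - k - 1) * (n - k - 2) * rho
            expected = max(1.0, 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * total)
            assert hamed_rao_factor(x, lag_policy="all") == pytest.approx(expected)

    def test_unknown_policy_rejected(self):
        with pytest.raises(InvalidInputError):
            hamed_rao_factor(np.arange(10.0), lag_policy="sometimes")


class TestModifiedMkTest:
    def test_perfect_monotone_trend(self):
        res = modified_mk_test(np.arange(20.0))
        assert res.p_value < 0.05
        assert res.sen_slope > 0
        assert res.significance_class == "p<0.05"

    def test_constant_series_is_null(self):
        res = modified_mk_test([5.0] * 10)
        assert res.s_statistic == 0
        assert res.z_score == 0.0
        assert res.p_value == 1.0
        assert res.sen_slope == 0.0

    @pytest.mark.parametrize("series", [s for s in FIXTURE_SERIES if len(set(s)) > 1])
    def test_raw_p_near_exact_permutation_p(self, series):
        """For n <= 7 the normal-approximation p (uncorrected variance) must
        track the exact permutation distribution of S over all orderings."""
        x = np.asarray(series)
        n = len(x)
        s_obs = abs(mk_s(x))
        s_values = [abs(brute_s(list(p))) for p in itertools.permutations(x)]
        p_exact = np.mean([s >= s_obs for s in s_values])
        res = modified_mk_test(x, lag_policy="all")
        # the continuity-corrected normal approximation tracks the exact
        # permutation p to within 0.05 at these lengths
        assert abs(res.p_value_raw - p_exact) < 0.05

    def test_corrected_and_raw_both_reported(self, rng):
        x = rng.normal(size=25).cumsum()
        res = modified_mk_test(x)
        assert 0 <= res.p_value <= 1 and 0 <= res.p_value_raw <= 1
        assert res.variance_corrected == pytest.approx(
            res.variance_raw * res.correction_factor
        )

    def test_sign_recovery_on_synthetic_deficit_series(self):
        """Slopes of +/-0.5 %/window with AR(1) noise (sd 5) must be
        recovered in sign at n = 30 in at least 90% of 500 seeds."""
        for beta in (-0.5, 0.5):
            hits = 0
            for seed in range(500):
                series = generate_deficit_series(
                    30, slope=beta, ar1_phi=0.3, noise_sd=5.0, seed=seed
                )
                if np.sign(sen_slope(series)) == np.sign(beta):
                    hits += 1
            assert hits / 500 >= 0.90

    def test_runs_on_clipped_series(self):
        series = np.clip(np.linspace(-130, 20, 25), -100.0, 0.0)
        res = modified_mk_test(series)
        assert np.isfinite(res.p_value)
        cp = pettitt_test(series)
        assert np.isfinite(cp.p_value)


class TestPettitt:
    def test_step_series(self):
        # ten 0s then ten 1s: every cross-pair concordant, K = 100 at tau = 10
        res = pettitt_test([0.0] * 10 + [1.0] * 10)
        assert res.tau_index == 10
        assert res.k_statistic == 100
        bk, bt = brute_pettitt_k([0.0] * 10 + [1.0] * 10)
        assert (res.k_statistic, res.tau_index) == (bk, bt)

    def test_constant_series(self):
        res = pettitt_test([4.0] * 8)
        assert res.k_statistic == 0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("series", FIXTURE_SERIES)
    def test_matches_double_loop_oracle(self, series):
        res = pettitt_test(series)
        bk, bt = brute_pettitt_k(series)
        assert res.k_statistic == bk
        assert res.tau_index == bt  # earliest argmax on ties

    def test_p_value_formula(self):
        x = [0.0] * 5 + [3.0] * 5
        res = pettitt_test(x)
        n, k = 10, res.k_statistic
        assert res.p_value == pytest.approx(2 * np.exp(-6 * k * k / (n**3 + n**2)))

    def test_window_labels_passed_through(self):
        res = pettitt_test(
            [0.0, 0.0, 0.0, 5.0, 5.0],
            window_labels=["1985-1987", "1986-1988", "1987-1989", "1988-1990", "1989-1991"],
        )
        assert res.tau_window_label == "1987-1989"

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            pettitt_test([1.0, 2.0, 3.0])


class TestClassifySignificance:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.04, "p<0.05"), (0.07, "p<0.1"), (0.2, "p<0.25"), (0.5, "ns"), (0.25, "ns")],
    )
    def test_ladder(self, p, expected):
        assert classify_significance(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_significance(1.5)


class TestInvariances:
    @given(
        shift=st.floats(min_value=-50, max_value=50),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(deadline=None, max_examples=40)
    def test_shift_invariance(self, shift, seed):
        x = np.random.default_rng(seed).normal(size=12)
        assert mk_s(x + shift) == mk_s(x)
        assert sen_slope(x + shift) == pytest.approx(sen_slope(x), abs=1e-9)
        assert pettitt_test(x + shift).k_statistic == pettitt_test(x).k_statistic

    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(deadline=None, max_examples=40)
    def test_positive_scaling(self, scale, seed):
        x = np.random.default_rng(seed).normal(size=12)
        assert mk_s(scale * x) == mk_s(x)
        assert sen_slope(scale * x) == pytest.approx(scale * sen_slope(x), rel=1e-9)

    def test_monotone_transform_invariance(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            y = np.exp(x)  # strictly increasing transform
            assert mk_s(y) == mk_s(x)
            assert pettitt_test(y).k_statistic == pettitt_test(x).k_statistic
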