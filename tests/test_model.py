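"""Unit and property tests for the biexponential decay core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endodecay import (
    BiexpParams,
    DomainError,
    ecl_at,
    evaluate,
    half_times,
    summarize,
    time_to_threshold,
)

from conftest import DONOR_MEAN


decay_params = st.builds(
    BiexpParams,
    a=st.floats(10.0, 500.0),
    b=st.floats(-1.0, -0.05),
    c=st.floats(500.0, 3000.0),
    d=st.floats(-0.05, -0.001),
)


class TestEvaluate:
    def test_t_zero_is_sum_of_scales(self, published_params):
        assert evaluate(published_params, 0.0) == pytest.approx(1757.5)

    def test_published_curve_at_ten_years(self, published_params):
        # Frozen independently with high-precision scalar arithmetic.
        assert round(evaluate(published_params, 120.0), 1) == 839.4

    def test_zero_rates_sum_scales_at_any_time(self):
        p = BiexpParams(1.0, 0.0, 1.0, 0.0)
        for t in (0.0, 5.0, 1e3):
            assert evaluate(p, t) == pytest.approx(2.0)

    def test_negative_time_rejected(self, published_params):
        with pytest.raises(DomainError):
            evaluate(published_params, -1.0)

    def test_vectorized_matches_scalar(self, published_params):
        ts = np.array([0.0, 1.0, 24.0])
        np.testing.assert_allclose(
            evaluate(published_params, ts),
            [evaluate(published_params, t) for t in ts],
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=decay_params)
    def test_strictly_decreasing_for_decay(self, params):
        ts = np.linspace(0.0, 240.0, 200)
        vals = evaluate(params, ts)
        assert np.all(np.diff(vals) < 0)


class TestHalfTimes:
    def test_published_late_half_time(self, published_params):
        _, late = half_times(published_params)
        assert round(late, 2) == 131.50

    def test_published_early_half_time(self, published_params):
        early, _ = half_times(published_params)
        assert early == pytest.approx(math.log(2) / 0.2298)
        assert round(early, 2) == 3.02

    def test_unit_half_time_by_definition(self):
        early, _ = half_times(BiexpParams(1.0, -math.log(2), 1.0, -0.001))
        assert early == pytest.approx(1.0)

    def test_early_always_before_late(self, published_params):
        early, late = half_times(published_params)
        assert early < late

    @pytest.mark.parametrize("b,d", [(0.1, -0.1), (-0.1, 0.0), (0.0, 0.0)])
    def test_non_decay_rates_rejected(self, b, d):
        with pytest.raises(DomainError):
            half_times(BiexpParams(1.0, b, 1.0, d))

    def test_single_phase_halving_self_consistency(self):
        # With the fast phase absent, advancing by one late half-time
        # exactly halves the curve.
        p = BiexpParams(0.0, -1.0, 1500.0, -0.005271)
        ht = math.log(2) / 0.005271
        for t in (0.0, 10.0, 100.0):
            assert evaluate(p, t + ht) == pytest.approx(evaluate(p, t) / 2.0)


class TestEclAt:
    @pytest.mark.parametrize("month,expected", [(36, 48), (60, 54), (120, 67)])
    def test_published_ecl_horizons(self, published_params, month, expected):
        assert round(ecl_at(published_params, month, DONOR_MEAN)) == expected

    def test_self_baseline_is_zero(self, published_params):
        v = evaluate(published_params, 12.0)
        assert ecl_at(published_params, 12.0, v) == pytest.approx(0.0)

    def test_non_positive_baseline_rejected(self, published_params):
        with pytest.raises(DomainError):
            ecl_at(published_params, 12.0, 0.0)


class TestTimeToThreshold:
    @pytest.mark.parametrize("threshold,expected", [(500, 218), (250, 349)])
    def test_published_crossings(self, published_params, threshold, expected):
        assert time_to_threshold(published_params, threshold) == expected

    def test_exact_integer_crossing_one_half_life(self):
        p = BiexpParams(0.0, -1.0, 1000.0, -math.log(2))
        assert time_to_threshold(p, 500.0) == 1

    def test_threshold_above_start_rejected(self, published_params):
        with pytest.raises(DomainError):
            time_to_threshold(published_params, 2000.0)

    def test_non_positive_threshold_rejected(self, published_params):
        with pytest.raises(DomainError):
            time_to_threshold(published_params, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params=decay_params, frac=st.floats(0.01, 0.9))
    def test_matches_whole_month_scan(self, params, frac):
        # Oracle: the last whole month at which the curve is still at or
        # above the threshold, found by brute-force scanning.
        threshold = frac * evaluate(params, 0.0)
        result = time_to_threshold(params, threshold)
        m = 0
        while evaluate(params, float(m + 1)) >= threshold:
            m += 1
        assert result == m

    def test_monotone_in_threshold(self, published_params):
        months = [
            time_to_threshold(published_params, th)
            for th in (1000.0, 750.0, 500.0, 250.0)
        ]
        assert months == sorted(months)
        assert len(set(months)) == len(months)

    def test_single_term_closed_form_limit(self):
        # When the fast phase has fully decayed at the crossing, the
        # continuous crossing matches ln(c/threshold)/|d|.
        p = BiexpParams(100.0, -2.0, 1500.0, -0.01)
        threshold = 400.0
        closed = math.log(p.c / threshold) / abs(p.d)
        assert time_to_threshold(p, threshold) == math.floor(closed)


class TestSummarize:
    def test_published_summary_bundle(self, published_params):
        s = summarize(published_params, DONOR_MEAN, (36, 60, 120), (500, 250))
        assert round(s.half_time_late_months, 2) == 131.50
        assert {m: round(v) for m, v in s.ecl_percent_at_months.items()} == {
            36: 48, 60: 54, 120: 67,
        }
        assert s.threshold_crossing_months == {500.0: 218, 250.0: 349}

    def test_empty_horizons_and_thresholds(self, published_params):
        s = summarize(published_params, DONOR_MEAN)
        assert s.ecl_percent_at_months == {}
        assert s.threshold_crossing_months == {}
        assert s.half_time_early_months < s.half_time_late_months

    def test_collapsed_single_phase_rejected(self):
        with pytest.raises(DomainError):
            summarize(BiexpParams(0.0, -1.0, 1500.0, -0.005), DONOR_MEAN)

    def test_ecl_increases_with_horizon(self, published_params):
        s = summarize(published_params, DONOR_MEAN, (12, 36, 60, 120, 240))
        vals = [s.ecl_percent_at_months[m] for m in (12, 36, 60, 120, 240)]
        assert vals == sorted(vals)


class TestParams:
    def test_canonical_ordering_swaps_phases(self):
        p = BiexpParams(1580.0, -0.005271, 177.5, -0.2298).canonical()
        assert p.as_tuple() == (177.5, -0.2298, 1580.0, -0.005271)

    def test_negative_scale_rejected(self):
        with pytest.raises(DomainError):
            BiexpParams(-1.0, -0.1, 1.0, -0.1)

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            BiexpParams(1.0, float("nan"), 1.0, -0.1)
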