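"""Linear trends, BH correction, seasonal decomposition and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytosize import trends as tr
from phytosize.validation import bh_exhaustive_gap, ols_oracle_gap


class TestLinearTrend:
    def test_exact_linear_fit_flagged(self):
        t = np.arange(50, dtype=float)
        fit = tr.linear_trend(t, 2.0 - 0.01 * t)
        assert fit.slope_per_month == pytest.approx(-0.01, abs=1e-12)
        assert fit.slope_per_year == pytest.approx(-0.12, abs=1e-12)
        assert fit.exact_fit and fit.p == 0.0

    def test_constant_series_convention(self):
        fit = tr.linear_trend(np.arange(10.0), np.full(10, 3.0))
        assert fit.slope_per_month == 0.0
        assert fit.p == 1.0

    def test_agrees_with_normal_equations_oracle(self):
        gaps = ols_oracle_gap(n_series=100, seed=0)
        assert gaps["max_slope_gap"] < 1e-10
        assert gaps["max_p_gap"] < 1e-10

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            tr.linear_trend(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            tr.linear_trend(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert tr.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        q = tr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equals_textbook_rejection_set_exhaustively(self):
        assert bh_exhaustive_gap(max_m=10, n_vectors=100, seed=1) == 0.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import fdrcorrection

        rng = np.random.default_rng(4)
        p = rng.random(25)
        assert np.allclose(tr.bh_adjust(p), fdrcorrection(p)[1])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_q_dominates_p_and_preserves_order(self, ps):
        q = tr.bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            tr.bh_adjust([0.5, 1.5])


class TestSTL:
    def test_trend_and_amplitude_recovery(self):
        t = np.arange(120)
        y = 0.5 * t + 3 * np.cos(2 * np.pi * t / 12)
        fit = tr.deseasoned_trend((t, y))
        assert abs(fit.slope_per_month - 0.5) / 0.5 < 0.05
        d = tr.stl_decompose((t, y))
        amp = (d.seasonal[12:-12].max() - d.seasonal[12:-12].min()) / 2
        assert abs(amp - 3) / 3 < 0.10

    def test_constant_series(self):
        d = tr.stl_decompose((np.arange(60), np.full(60, 7.0)))
        assert np.abs(d.seasonal).max() < 1e-8
        assert np.abs(d.trend - 7.0).max() < 1e-8

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        t = np.arange(96)
        y = 0.1 * t + np.cos(2 * np.pi * t / 12) + rng.normal(0, 1, 96)
        d = tr.stl_decompose((t, y))
        assert np.abs(d.trend + d.seasonal + d.residual - d.observed).max() < 1e-10

    def test_gaps_interpolated_and_flagged(self):
        t = np.arange(72)
        y = 0.2 * t + np.cos(2 * np.pi * t / 12)
        keep = np.ones(72, bool)
        keep[[10, 30, 31]] = False
        d = tr.stl_decompose((t[keep], y[keep]))
        assert d.interpolated.sum() == 3
        assert d.interpolated[[10, 30, 31]].all()

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            tr.stl_decompose((np.arange(20), np.random.default_rng(0).normal(size=20)))


class TestDeseasonedTrend:
    def test_pure_seasonal_signal_not_significant(self):
        rng = np.random.default_rng(3)
        t = np.arange(120)
        y = 3 * np.cos(2 * np.pi * t / 12) + rng.normal(0, 0.3, 120)
        fit = tr.deseasoned_trend((t, y))
        assert abs(fit.slope_per_month) < 0.01
        assert fit.p > 0.05

    def test_matches_direct_fit_when_no_seasonality(self):
        rng = np.random.default_rng(6)
        t = np.arange(96)
        y = 5 + 0.03 * t + rng.normal(0, 0.2, 96)
        direct = tr.linear_trend(t.astype(float), y)
        deseason = tr.deseasoned_trend((t, y))
        assert deseason.slope_per_month == pytest.approx(direct.slope_per_month, rel=0.05)


class TestClassification:
    @pytest.mark.parametrize(
        "slope,p,expected",
        [(-2.0, 0.01, "decline"), (-2.0, 0.20, "none"), (2.0, 0.001, "increase"), (0.0, 0.001, "none")],
    )
    def test_three_way_label(self, slope, p, expected):
        res = tr.TrendResult(slope, 12 * slope, 1.0, p, 0.5, 100)
        assert tr.classify_trend(res) == expected

    def test_q_used_when_requested(self):
        res = tr.TrendResult(-2.0, -24.0, 1.0, 0.01, 0.5, 100, q=0.20)
        assert tr.classify_trend(res) == "decline"
        assert tr.classify_trend(res, use_q=True) == "none"


class TestAnnualRelativeChange:
    def test_percent_per_year(self):
        res = tr.TrendResult(-25 / 12, -25.0, 1000.0, 0.01, 0.5, 100)
        assert tr.annual_relative_change(res) == pytest.approx(-2.5)

    def test_zero_slope_zero_change(self):
        res = tr.TrendResult(0.0, 0.0, 1000.0, 1.0, 0.0, 100)
        assert tr.annual_relative_change(res) == 0.0

    def test_invariant_to_series_scaling(self):
        rng = np.random.default_rng(8)
        t = np.arange(60, dtype=float)
        y = 100 + 0.5 * t + rng.normal(0, 1, 60)
        a = tr.annual_relative_change(tr.linear_trend(t, y))
        b = tr.annual_relative_change(tr.linear_trend(t, 7.3 * y))
        assert a == pytest.approx(b)

    def test_nonpositive_baseline_missing(self):
        res = tr.TrendResult(1.0, 12.0, -5.0, 0.01, 0.5, 100)
        assert np.isnan(tr.annual_relative_change(res))
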