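"""Thresholds, smoothing-spline growth fits, median slopes, regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ols_closed_form, spline_oracle
from recruitpipe.core import ValidationError
from recruitpipe.recruit import (
    GrowthFit,
    LevelSeries,
    RecruitSlope,
    aggregate_low_freq,
    compute_snr,
    estimate_threshold,
    fit_growth_spline,
    median_slope,
    regress_slope_vs_threshold,
)

LEVELS = np.arange(10.0, 81.0, 5.0)


def _series(response, snr=None, noise_floor=None, levels=LEVELS, kind="anow_magnitude"):
    return LevelSeries(frequency=480.0, label="480", levels=levels,
                       response=np.asarray(response, float), measure_kind=kind,
                       noise_floor=noise_floor, snr=snr)


class TestSnr:
    def test_db_subtraction(self):
        s = _series([10.0, 4.0], noise_floor=[4.0, 4.0], levels=[10.0, 15.0])
        out = compute_snr(s)
        assert out.snr[0] == 6.0
        assert out.snr[1] == 0.0

    def test_cap_microvolt_series_converted_to_db(self):
        s = _series([10.0, 1.0], noise_floor=[1.0, 1.0], levels=[10.0, 15.0],
                    kind="cap_p2p")
        out = compute_snr(s)
        assert out.snr[0] == pytest.approx(20.0)
        assert out.snr[1] == pytest.approx(0.0)

    def test_delay_series_has_no_own_snr(self):
        s = _series([1.0, 0.9], levels=[10.0, 15.0], kind="anow_phase_delay")
        with pytest.raises(ValidationError, match="delay"):
            compute_snr(s)


class TestThreshold:
    @pytest.mark.parametrize("snr, expected", [
        ([-2, 3, 8, 12, 20], 20.0),          # first run-of-2 starts at the 3rd level
        ([1, 2, 3, 4, 5], None),             # never reaches criterion
        ([2, 9, 2, 8, 9], 25.0),             # isolated excursion at level 2 ignored
        ([9, 9, 9, 9, 9], 10.0),             # qualifies from the lowest level
        ([2, 2, 2, 2, 9], None),             # final level alone cannot qualify
    ])
    def test_run_of_two_rule(self, snr, expected):
        s = _series(np.zeros(5), snr=snr, levels=np.arange(10.0, 31.0, 5.0))
        assert estimate_threshold(s) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10.0, 30.0), min_size=2, max_size=15))
    def test_matches_first_adjacent_pair_rule_on_random_series(self, snr):
        levels = 10.0 + 5.0 * np.arange(len(snr))
        s = _series(np.zeros(len(snr)), snr=snr, levels=levels)
        got = estimate_threshold(s)
        ok = [v >= 6.0 for v in snr]
        expected = next((levels[i] for i in range(len(ok) - 1)
                         if ok[i] and ok[i + 1]), None)
        assert got == expected

    def test_criterion_is_configurable(self):
        s = _series(np.zeros(3), snr=[7.0, 7.0, 7.0], levels=[10.0, 15.0, 20.0])
        assert estimate_threshold(s, criterion=6.0) == 10.0
        assert estimate_threshold(s, criterion=9.0) is None


class TestGrowthSpline:
    def test_affine_data_reproduced_exactly_any_weights(self, rng):
        y = 0.4 * LEVELS - 7.0
        for _ in range(5):
            w = rng.uniform(0.1, 40.0, LEVELS.size)
            fit = fit_growth_spline(_series(y), weights=w)
            assert np.allclose(fit.fitted, 0.4 * fit.grid - 7.0, atol=1e-8)
            assert np.allclose(fit.derivative, 0.4, atol=1e-8)

    def test_grid_spacing_and_span(self):
        fit = fit_growth_spline(_series(0.5 * LEVELS), weights=np.ones(LEVELS.size))
        assert fit.grid[0] == 10.0 and fit.grid[-1] == 80.0
        assert np.allclose(np.diff(fit.grid), 1.0)

    def test_zero_weight_points_are_inert(self, rng):
        snr = np.full(LEVELS.size, 20.0)
        snr[:3] = 2.0  # below criterion -> weight 0
        y = 0.3 * LEVELS + rng.normal(0, 0.5, LEVELS.size)
        fit_a = fit_growth_spline(_series(y.copy(), snr=snr))
        y2 = y.copy()
        y2[:3] += 999.0  # perturb only zero-weight levels
        fit_b = fit_growth_spline(_series(y2, snr=snr))
        assert np.array_equal(fit_a.fitted, fit_b.fitted)
        assert np.array_equal(fit_a.derivative, fit_b.derivative)

    def test_matches_independent_penalized_spline_solver(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            y = 0.02 * LEVELS**2 + rng.normal(0, 1, LEVELS.size)
            snr = np.linspace(8, 30, LEVELS.size)
            fit = fit_growth_spline(_series(y, snr=snr))
            orc = spline_oracle(LEVELS, y, np.clip(snr, 0, None), 0.005)
            assert np.abs(fit.fitted - orc(fit.grid)).max() < 1e-8

    def test_too_few_weighted_points_rejected(self):
        snr = np.array([10.0, 10.0, 10.0, 2.0, 2.0])
        s = _series(np.zeros(5), snr=snr, levels=np.arange(10.0, 31.0, 5.0))
        with pytest.raises(ValidationError, match="4 levels"):
            fit_growth_spline(s)


class TestMedianSlope:
    def _fit(self, deriv):
        grid = np.arange(10.0, 10.0 + deriv.size)
        return GrowthFit(grid=grid, fitted=np.zeros_like(grid), derivative=deriv,
                         smoothing_coefficient=0.005, weights_used=np.ones(4))

    def test_constant_derivative(self):
        fit = self._fit(np.ones(30))
        s = median_slope(fit, threshold=20.0)
        assert s.median_slope == 1.0
        assert s.n_grid_points_used == 20

    def test_piecewise_derivative_counting(self):
        deriv = np.concatenate([np.full(10, 2.0), np.full(20, 0.5)])
        s = median_slope(self._fit(deriv), threshold=10.0)
        assert s.median_slope == 0.5

    def test_absence_propagates(self):
        fit = self._fit(np.ones(10))
        assert median_slope(fit, threshold=None) is None
        assert median_slope(fit, threshold=99.0) is None


class TestRegression:
    def test_exact_line(self):
        r = regress_slope_vs_threshold([(0, 0), (10, 1), (20, 2)])
        assert r.slope == pytest.approx(0.1, abs=1e-12)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)
        assert r.ci_low <= r.slope <= r.ci_high

    def test_matches_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.1, 2.9, 5.2, 7.8, 12.4])
        r = regress_slope_vs_threshold(list(zip(x, y)))
        ref = ols_closed_form(x, y)
        for key in ("slope", "intercept", "r_squared", "p_value", "ci_low", "ci_high"):
            assert getattr(r, key) == pytest.approx(ref[key], abs=1e-8)

    def test_degenerate_and_undersized_inputs(self):
        with pytest.raises(ValidationError, match="degenerate"):
            regress_slope_vs_threshold([(5, 1), (5, 2), (5, 3)])
        with pytest.raises(ValidationError, match=">= 3"):
            regress_slope_vs_threshold([(1, 1), (2, 2)])


class TestAggregateLowFreq:
    def _slope(self, freq, slope, thr=30.0):
        return RecruitSlope(frequency=freq, label=f"{freq:g}", threshold=thr,
                            median_slope=slope, n_grid_points_used=10)

    def test_mean_over_low_frequencies(self):
        slopes = [self._slope(300, 0.3), self._slope(480, 0.5),
                  self._slope(720, 0.7), self._slope(1020, 0.9)]
        agg = aggregate_low_freq(slopes, control_reference_threshold=20.0)
        assert agg == (pytest.approx(0.6), pytest.approx(10.0))

    def test_high_frequencies_excluded(self):
        slopes = [self._slope(480, 0.5), self._slope(8000, 5.0)]
        agg = aggregate_low_freq(slopes, control_reference_threshold=30.0)
        assert agg == (pytest.approx(0.5), pytest.approx(0.0))

    def test_single_frequency_is_identity(self):
        agg = aggregate_low_freq([self._slope(300, 0.42, thr=35.0)], 20.0)
        assert agg == (pytest.approx(0.42), pytest.approx(15.0))

    def test_none_qualifying_yields_absence(self):
        assert aggregate_low_freq([None, self._slope(8000, 1.0)], 20.0) is None
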