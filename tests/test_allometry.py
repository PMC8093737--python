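"""Log-log allometry: OLS values, prediction errors, bands and overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from shrubmass import (CalibSample, LogLogAllometry, PredictionBand,
                       band_overlap, fit_loglog, fit_pe_model,
                       prediction_band)


def _closed_form_ols(lx, ly):
    """Normal-equations oracle, independent of the fitting path."""
    xbar, ybar = lx.mean(), ly.mean()
    sxx = np.sum((lx - xbar) ** 2)
    slope = np.sum((lx - xbar) * (ly - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = ly - intercept - slope * lx
    s = np.sqrt(np.sum(resid**2) / (lx.size - 2))
    return intercept, slope, s


class TestFit:
    def test_exact_power_law(self, noiseless_tip_fit):
        assert noiseless_tip_fit.intercept_ == pytest.approx(np.log(2.0), abs=1e-12)
        assert noiseless_tip_fit.slope_ == pytest.approx(2.5, abs=1e-12)
        assert noiseless_tip_fit.residual_scale_ == pytest.approx(0.0, abs=1e-10)
        assert noiseless_tip_fit.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_four_point_fit(self, four_point_fit):
        assert four_point_fit.slope_ == pytest.approx(2.52, abs=1e-10)
        assert four_point_fit.intercept_ == pytest.approx(0.97, abs=1e-10)
        assert four_point_fit.residual_scale_ == pytest.approx(
            np.sqrt(0.018 / 2), abs=1e-10)
        assert four_point_fit.n_ == 4
        assert four_point_fit.df_ == 2
        assert four_point_fit.mean_logx_ == pytest.approx(1.5)
        assert four_point_fit.sxx_ == pytest.approx(5.0)

    def test_matches_normal_equations_oracle_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(4, 30)
            d = rng.uniform(0.5, 40.0, n)
            m = 0.1 * d**2.3 * np.exp(rng.normal(0, 0.4, n))
            fit = LogLogAllometry().fit(d, m)
            a, b, s = _closed_form_ols(np.log(d), np.log(m))
            assert fit.intercept_ == pytest.approx(a, abs=1e-10)
            assert fit.slope_ == pytest.approx(b, abs=1e-10)
            assert fit.residual_scale_ == pytest.approx(s, abs=1e-10)

    def test_se_fit_matches_statsmodels_prediction(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        d = rng.uniform(1, 20, 25)
        m = 0.07 * d**2.4 * np.exp(rng.normal(0, 0.3, 25))
        fit = LogLogAllometry().fit(d, m)
        res = sm.OLS(np.log(m), sm.add_constant(np.log(d))).fit()
        newx = np.array([1.5, 5.0, 18.0])
        pred = res.get_prediction(sm.add_constant(np.log(newx)))
        mu, se_fit, _ = fit.predict_log(newx)
        np.testing.assert_allclose(mu, pred.predicted_mean, rtol=1e-10)
        np.testing.assert_allclose(se_fit, pred.se_mean, rtol=1e-8)

    @pytest.mark.parametrize("samples", [
        [CalibSample(2.0, 1.0), CalibSample(3.0, 2.0)],       # too few
        [CalibSample(2.0, 1.0)] * 4,                           # zero spread
    ])
    def test_invalid_inputs_rejected(self, samples):
        with pytest.raises(ValueError):
            fit_loglog(samples)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            LogLogAllometry().fit([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            CalibSample(2.0, 0.0)


class TestPrediction:
    def test_zero_noise_prediction_is_exact(self, noiseless_tip_fit):
        mu, se_fit, se_pred = noiseless_tip_fit.predict_log(5.0)
        assert np.exp(mu) == pytest.approx(2.0 * 5.0**2.5, rel=1e-10)
        assert se_fit == pytest.approx(0.0, abs=1e-10)
        assert se_pred == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_standard_errors(self, four_point_fit):
        mu, se_fit, se_pred = four_point_fit.predict_log(np.exp(1.5))
        assert mu == pytest.approx(4.75, abs=1e-10)
        assert se_fit == pytest.approx(0.0474341649, abs=1e-8)
        assert se_pred == pytest.approx(0.1060660172, abs=1e-8)

    def test_se_pred_dominates_components(self, four_point_fit):
        d = np.linspace(0.1, 100, 500)
        _, se_fit, se_pred = four_point_fit.predict_log(d)
        assert np.all(se_pred >= se_fit)
        assert np.all(se_pred >= four_point_fit.residual_scale_)

    def test_back_transform_matches_power_function(self, four_point_fit):
        d = np.linspace(0.1, 100, 200)
        mu, _, _ = four_point_fit.predict_log(d)
        a = np.exp(four_point_fit.intercept_)
        np.testing.assert_allclose(np.exp(mu), a * d**four_point_fit.slope_,
                                   rtol=1e-10)

    def test_hand_computed_interval(self, four_point_fit):
        point, lwr, upr = four_point_fit.prediction_interval(np.exp(1.5))
        assert point == pytest.approx(115.584, abs=0.01)
        assert lwr == pytest.approx(73.232, abs=0.01)
        assert upr == pytest.approx(182.430, abs=0.01)

    def test_interval_collapses_without_noise(self, noiseless_tip_fit):
        point, lwr, upr = noiseless_tip_fit.prediction_interval(4.0)
        assert lwr == pytest.approx(point, rel=1e-8)
        assert upr == pytest.approx(point, rel=1e-8)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.5, max_value=50.0))
    def test_multiplicative_symmetry(self, four_point_fit, diameter):
        point, lwr, upr = four_point_fit.prediction_interval(diameter)
        assert lwr * upr == pytest.approx(point**2, rel=1e-9)
        assert lwr <= point <= upr

    def test_rejects_bad_diameter_and_level(self, four_point_fit):
        with pytest.raises(ValueError):
            four_point_fit.predict_log(-1.0)
        with pytest.raises(ValueError):
            four_point_fit.prediction_interval(5.0, level=1.5)


class TestBand:
    def test_grid_point_count(self, four_point_fit):
        band = four_point_fit.band(2.5, 7.5, step=0.01)
        assert band.grid_cm.size == 501
        assert band.grid_cm[0] == pytest.approx(2.5)
        assert band.grid_cm[-1] == pytest.approx(7.5)

    def test_band_matches_pointwise_intervals(self, four_point_fit):
        band = four_point_fit.band(2.5, 7.5, step=0.5)
        for i, d in enumerate(band.grid_cm):
            point, lwr, upr = four_point_fit.prediction_interval(d)
            assert band.point_kg[i] == pytest.approx(point, rel=1e-12)
            assert band.lwr_kg[i] == pytest.approx(lwr, rel=1e-12)
            assert band.upr_kg[i] == pytest.approx(upr, rel=1e-12)

    def test_uncertainty_increases_with_diameter(self, four_point_fit):
        band = four_point_fit.band(1.0, 50.0, step=0.1)
        assert np.all(np.diff(band.uncertainty_kg) > 0)

    def test_zero_noise_band_has_zero_width(self, noiseless_tip_fit):
        band = noiseless_tip_fit.band(2.5, 7.5, step=0.1)
        np.testing.assert_allclose(band.uncertainty_kg, 0.0, atol=1e-8)

    def test_empty_grid_rejected(self, four_point_fit):
        with pytest.raises(ValueError):
            four_point_fit.band(7.5, 2.5)


def _flat_band(lwr, upr, n=11):
    grid = np.linspace(2.0, 4.0, n)
    mid = np.sqrt(lwr * upr) if lwr > 0 else (lwr + upr) / 2
    return PredictionBand(grid, np.full(n, mid), np.full(n, float(lwr)),
                          np.full(n, float(upr)))


class TestBandOverlap:
    def test_identical_bands_fully_overlap(self, four_point_fit):
        a = four_point_fit.band(2.5, 7.5, step=0.1)
        b = four_point_fit.band(2.5, 7.5, step=0.1)
        assert band_overlap(a, b) == pytest.approx(1.0)

    def test_disjoint_bands_do_not_overlap(self):
        assert band_overlap(_flat_band(1.0, 2.0), _flat_band(5.0, 9.0)) == 0.0

    def test_half_overlap_interval_arithmetic(self):
        assert band_overlap(_flat_band(1.0, 3.0), _flat_band(2.0, 4.0)) == \
            pytest.approx(0.5)

    def test_mismatched_grids_rejected(self, four_point_fit):
        a = four_point_fit.band(2.5, 7.5, step=0.1)
        b = four_point_fit.band(2.5, 7.5, step=0.2)
        with pytest.raises(ValueError):
            band_overlap(a, b)

    def test_similar_fits_overlap_strongly(self):
        # two fits of the same underlying allometry should nearly share bands
        rng = np.random.default_rng(3)
        d1, d2 = rng.uniform(2.5, 7.5, (2, 60))
        fit_a = LogLogAllometry().fit(d1, 0.07 * d1**2.44 * np.exp(rng.normal(0, 0.3, 60)))
        fit_b = LogLogAllometry().fit(d2, 0.07 * d2**2.44 * np.exp(rng.normal(0, 0.3, 60)))
        frac = band_overlap(fit_a.band(2.5, 7.5), fit_b.band(2.5, 7.5))
        assert frac > 0.8


class TestPEModel:
    def test_exact_power_law_widths(self):
        grid = np.linspace(2.0, 10.0, 50)
        width = 3.0 * grid**2.1
        band = PredictionBand(grid, grid, grid - width / 2, grid + width / 2)
        pe = fit_pe_model(band)
        assert pe.k == pytest.approx(3.0, rel=1e-10)
        assert pe.p == pytest.approx(2.1, rel=1e-10)

    def test_two_point_exact_solve(self):
        grid = np.array([1.0, np.e])
        width = np.array([2.0, 2.0 * np.e])
        band = PredictionBand(grid, grid, grid, grid + width)
        pe = fit_pe_model(band)
        assert pe.k == pytest.approx(2.0, rel=1e-10)
        assert pe.p == pytest.approx(1.0, rel=1e-10)

    def test_zero_width_rejected(self):
        grid = np.linspace(2.5, 7.5, 11)
        point = 0.07 * grid**2.4
        band = PredictionBand(grid, point, point.copy(), point.copy())
        with pytest.raises(ValueError):
            fit_pe_model(band)


def test_pi_coverage_on_simulated_data():
    """Refit-and-predict coverage of the 95% back-transformed interval.

    Masses are simulated from the fitted model's own assumptions; the
    t-based prediction interval should cover fresh observations at the
    nominal rate. Uses a cluster (per-refit) Monte-Carlo standard error
    because points sharing a fit are correlated.
    """
    rng = np.random.default_rng(42)
    a, b, s = np.log(0.07), 2.437, 0.45
    per_fit = []
    for _ in range(30):
        d = rng.uniform(2.5, 7.5, 60)
        m = np.exp(a + b * np.log(d) + rng.normal(0, s, 60))
        fit = LogLogAllometry().fit(d, m)
        d_new = rng.uniform(2.5, 7.5, 60)
        m_new = np.exp(a + b * np.log(d_new) + rng.normal(0, s, 60))
        _, lwr, upr = fit.prediction_interval(d_new)
        per_fit.append(np.mean((m_new >= lwr) & (m_new <= upr)))
    per_fit = np.asarray(per_fit)
    se = per_fit.std(ddof=1) / np.sqrt(per_fit.size)
    assert abs(per_fit.mean() - 0.95) <= 2 * se + 1e-9
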