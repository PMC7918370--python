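import numpy as np
import pytest

from tsgc import (
    ARIMAOrder,
    ARIMASettings,
    choose_d,
    exhaustive_select,
    fit_all_residuals,
    fit_arima,
    fit_trend,
    stepwise_select,
)
from tsgc.errors import FitError, SeriesLengthError


def ar1(rng, n, phi, sd=1.0, burn=100):
    e = rng.normal(0, sd, n + burn)
    y = np.empty(n + burn)
    y[0] = e[0] / np.sqrt(1 - phi**2)
    for t in range(1, n + burn):
        y[t] = phi * y[t - 1] + e[t]
    return y[burn:]


class TestChooseD:
    def test_ramp_needs_one_difference(self):
        rng = np.random.default_rng(41)
        y = 0.01 * np.arange(121) + rng.normal(0, 0.005, 121)
        assert choose_d(y, min_d=0) == 1

    def test_min_d_floor_respected(self):
        rng = np.random.default_rng(42)
        assert choose_d(rng.normal(size=121), min_d=1) == 1

    def test_white_noise_needs_no_difference(self):
        rng = np.random.default_rng(43)
        assert choose_d(rng.normal(size=121), min_d=0) == 0

    def test_short_series_rejected(self):
        with pytest.raises(SeriesLengthError):
            choose_d(np.arange(10.0), min_d=0)


class TestFitARIMA:
    def test_random_walk_identity(self):
        """ARIMA(0,1,0) one-step prediction is the previous value."""
        rng = np.random.default_rng(44)
        incr = rng.normal(size=80)
        y = np.cumsum(incr)
        fit = fit_arima(y, ARIMAOrder(0, 1, 0))
        np.testing.assert_allclose(fit.fitted[1:], y[:-1], atol=1e-8)
        np.testing.assert_allclose(fit.residuals[1:], incr[1:], atol=1e-8)

    def test_ar1_coefficient_recovery(self):
        rng = np.random.default_rng(45)
        y = ar1(rng, 2000, 0.8)
        fit = fit_arima(y, ARIMAOrder(1, 0, 0, trend="c"))
        assert fit.ar_coeffs[0] == pytest.approx(0.8, abs=0.05)

    def test_ma1_coefficient_recovery(self):
        rng = np.random.default_rng(46)
        e = rng.normal(size=2001)
        y = e[1:] + 0.5 * e[:-1]
        fit = fit_arima(y, ARIMAOrder(0, 0, 1, trend="c"))
        assert fit.ma_coeffs[0] == pytest.approx(0.5, abs=0.07)

    def test_reconstruction_exact(self):
        rng = np.random.default_rng(47)
        y = ar1(rng, 150, 0.6)
        for order in [ARIMAOrder(1, 0, 0), ARIMAOrder(1, 1, 1), ARIMAOrder(0, 1, 2)]:
            fit = fit_arima(y, order)
            np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-12)

    def test_ar_roots_outside_unit_circle(self):
        rng = np.random.default_rng(48)
        y = ar1(rng, 300, 0.9)
        fit = fit_arima(y, ARIMAOrder(2, 0, 0))
        # phi(z) = 1 - phi1 z - phi2 z^2; stationarity: roots outside unit circle
        roots = np.roots(np.r_[-fit.ar_coeffs[::-1], 1.0])
        assert np.all(np.abs(roots) > 1.0 - 1e-8)

    def test_series_too_short(self):
        with pytest.raises(SeriesLengthError):
            fit_arima(np.arange(4.0), ARIMAOrder(2, 1, 2))

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            ARIMAOrder(1, 3, 0)
        with pytest.raises(ValueError):
            ARIMAOrder(1, 0, 0, seasonal=(1, 0, 0, 1))


class TestStepwiseSelection:
    def test_ar1_selected_close_to_truth(self):
        rng = np.random.default_rng(49)
        y = ar1(rng, 300, 0.8)
        order = stepwise_select(y, d=0, p_max=3, q_max=3)
        assert order.p >= 1
        assert order.q <= 1

    def test_white_noise_mostly_selects_empty_model(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            order = stepwise_select(rng.normal(size=300), d=0, p_max=2, q_max=2)
            hits += order.pdq == (0, 0, 0)
        assert hits >= 11  # majority of replicates

    def test_degenerate_bounds_skip_search(self):
        rng = np.random.default_rng(50)
        y = np.cumsum(rng.normal(size=60))
        order = stepwise_select(y, d=1, p_max=0, q_max=0, drift=False)
        assert order.pdq == (0, 1, 0)

    def test_within_two_aicc_of_exhaustive(self):
        """Stepwise search is near-optimal on a bounded grid."""
        from tsgc.arima import fit_arima as _fit

        for seed in (60, 61, 62):
            rng = np.random.default_rng(seed)
            y = ar1(rng, 200, 0.7) + 0.3 * rng.normal(size=200)
            sw = stepwise_select(y, d=0, p_max=3, q_max=3)
            sw_aicc = _fit(y, sw).aicc
            _, best_aicc = exhaustive_select(y, d=0, p_max=3, q_max=3)
            assert sw_aicc <= best_aicc + 2.0


class TestFitAllResiduals:
    def test_white_residuals_give_trivial_models(self, small_iid_panel):
        panel, _ = small_iid_panel
        lmm_fit = fit_trend(panel)
        models = fit_all_residuals(
            lmm_fit, ARIMASettings(min_d=0, p_max=2, q_max=2, drift=False)
        )
        orders = [f.order.pdq for f in models.fits.values()]
        trivial = sum(o == (0, 0, 0) for o in orders)
        assert trivial >= len(orders) // 2
        assert models.whiteness.overall_pass

    def test_ar_residuals_whitened_with_forced_difference(self, small_ar_panel):
        panel, _ = small_ar_panel
        lmm_fit = fit_trend(panel)
        models = fit_all_residuals(
            lmm_fit, ARIMASettings(min_d=1, p_max=2, q_max=2)
        )
        assert all(f.order.d >= 1 for f in models.fits.values())
        assert models.whiteness.mean_fraction <= 0.10

    def test_reconstruction_per_subject(self, small_ar_panel):
        panel, _ = small_ar_panel
        lmm_fit = fit_trend(panel)
        models = fit_all_residuals(
            lmm_fit, ARIMASettings(min_d=1, p_max=1, q_max=1, drift=False)
        )
        resid = lmm_fit.residual_series()
        for subj, fit in models.fits.items():
            np.testing.assert_allclose(
                fit.fitted + fit.residuals, resid[subj], atol=1e-12
            )

    def test_empty_input_rejected(self, small_iid_panel):
        panel, _ = small_iid_panel
        lmm_fit = fit_trend(panel)
        lmm_fit = type(lmm_fit)(**{**lmm_fit.__dict__})
        lmm_fit.data = lmm_fit.data.iloc[0:0]
        with pytest.raises(FitError):
            fit_all_residuals(lmm_fit)
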