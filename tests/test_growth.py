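import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenorobust import (
    CalibrationModel,
    GrowthFit,
    TimeSeriesWell,
    apply_qc,
    compute_lag,
    fit_growth_curve,
    gv_to_od,
)
from phenorobust.calibration import CalibrationError
from phenorobust.growth import GrowthFitError


class TestGvToOd:
    def test_zero_at_blank(self):
        cal = CalibrationModel()
        assert gv_to_od(26.3, cal) == 0.0

    def test_value_at_gv_100_matches_hand_evaluation(self):
        # independent evaluation of a·Δ^b + c·Δ^d + e·Δ^f at Δ = 100 − 26.3
        delta = 100.0 - 26.3
        expected = (
            0.019 * delta**1.0
            + 3.82e-6 * delta**2.66
            + 3.111e-22 * delta**10.5
        )
        assert gv_to_od(100.0, CalibrationModel()) == pytest.approx(expected, rel=1e-12)

    def test_below_blank_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert gv_to_od(20.0, CalibrationModel()) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(
        gv1=st.floats(min_value=26.3, max_value=300.0),
        gv2=st.floats(min_value=26.3, max_value=300.0),
    )
    def test_monotone(self, gv1, gv2):
        cal = CalibrationModel()
        lo, hi = sorted([gv1, gv2])
        assert gv_to_od(lo, cal) <= gv_to_od(hi, cal)

    def test_missing_constants_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationModel(a=float("nan"))

    def test_pluggable_calibration_form(self):
        cal = CalibrationModel(od_from_gv=lambda d: 0.01 * d)
        assert gv_to_od(126.3, cal) == pytest.approx(1.0)


def _well(times, values, kind="OD"):
    return TimeSeriesWell("A1", np.asarray(times, float), np.asarray(values, float),
                          "S", "c", 1, signal_kind=kind)


class TestFitGrowthCurve:
    def test_noiseless_exponential_recovers_rate(self):
        t = np.linspace(0, 10, 50)
        y = 0.02 * np.exp(0.30 * t)
        fit = fit_growth_curve(_well(t, y))
        assert fit.grew
        assert fit.mu_max == pytest.approx(0.30, rel=0.02)
        assert fit.r_squared > 0.999

    def test_constant_series_is_no_growth(self):
        fit = fit_growth_curve(_well(np.arange(10.0), np.full(10, 5.0)))
        assert not fit.grew and fit.mu_max == 0.0 and np.isnan(fit.lag)

    def test_three_phase_curve_rate_within_5pct(self):
        # flat ~5 h, exponential near 0.4/h, plateau (logistic in log space);
        # the oracle is numeric differentiation of the generating function
        A, mu, tm = np.log(2.0 / 0.02), 0.4, 10.0
        logcurve = lambda t: np.log(0.02) + A / (1 + np.exp(-4 * mu / A * (t - tm)))
        t = np.arange(0, 24.01, 0.25)
        dense = np.linspace(0, 24, 20001)
        mu_oracle = float(np.max(np.gradient(logcurve(dense), dense)))
        fit = fit_growth_curve(_well(t, np.exp(logcurve(t))))
        assert mu_oracle == pytest.approx(0.4, rel=1e-3)
        assert fit.mu_max == pytest.approx(mu_oracle, rel=0.05)

    def test_nonpositive_values_without_blank_rejected(self):
        with pytest.raises(GrowthFitError, match="nonpositive"):
            fit_growth_curve(_well(np.arange(5.0), [0.0, 1.0, 2.0, 4.0, 8.0]))

    def test_flat_noisy_baseline_fails_qc(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 48.01, 0.5)
        gv = 26.3 + 5.0 * np.exp(rng.normal(0, 0.03, t.size))
        fit = apply_qc(fit_growth_curve(_well(t, gv, kind="GV"), blank=26.3))
        assert not fit.grew and fit.mu_max == 0.0


class TestComputeLag:
    def _fit(self, **kw):
        base = dict(well_id="A1", mu_max=0.4, lag=np.nan, r_squared=1.0, y0=0.0,
                    inflection_time=10.0, inflection_value=2.0, grew=True)
        base.update(kw)
        return GrowthFit(**base)

    def test_hand_computed_intersection(self):
        # tangent of slope 0.4 through (10 h, 2.0) meets y0 = 0 at t = 5 h
        assert compute_lag(self._fit()) == pytest.approx(5.0)

    def test_tangent_through_origin_gives_zero(self):
        fit = self._fit(inflection_time=5.0, inflection_value=2.0, mu_max=0.4)
        assert compute_lag(fit) == pytest.approx(0.0)

    def test_no_growth_gives_missing(self):
        fit = self._fit(grew=False, mu_max=0.0)
        assert np.isnan(compute_lag(fit))

    def test_negative_lag_clamps_with_warning(self):
        fit = self._fit(inflection_time=1.0, inflection_value=2.0, mu_max=0.4)
        with pytest.warns(UserWarning, match="negative lag"):
            assert compute_lag(fit) == 0.0


class TestApplyQc:
    def _fit(self, r2):
        return GrowthFit("A1", 0.3, 2.0, r2, 0.0, 8.0, 2.0, True)

    def test_poor_fit_censored(self):
        out = apply_qc(self._fit(0.95))
        assert out.mu_max == 0.0 and np.isnan(out.lag) and not out.grew

    def test_good_fit_unchanged(self):
        fit = self._fit(0.999)
        assert apply_qc(fit) is fit

    def test_boundary_is_strict(self):
        fit = self._fit(0.99)
        assert apply_qc(fit) is fit

    @settings(deadline=None, derandomize=True)
    @given(r2=st.floats(min_value=0.0, max_value=1.0))
    def test_idempotent(self, r2):
        once = apply_qc(self._fit(r2))
        assert apply_qc(once) is once

    def test_threshold_validated(self):
        with pytest.raises(GrowthFitError, match="threshold"):
            apply_qc(self._fit(0.5), r2_threshold=1.5)


class TestParameterRecovery:
    @pytest.mark.parametrize("mu,lam", [(0.1, 2.0), (0.3, 5.0), (0.5, 9.0)])
    def test_gompertz_grid(self, mu, lam):
        """Noiseless Gompertz curves over the physiological grid recover
        μmax within 5% and the tangent lag within 0.5 h."""
        t = np.arange(0, 48.01, 0.5)
        y0, A = np.log(0.8), 5.5
        y = y0 + A * np.exp(-np.exp(mu * np.e / A * (lam - t) + 1.0))
        lag_true = lam + (y[0] - y0) / mu  # tangent lag vs first-timepoint baseline
        fit = fit_growth_curve(_well(t, np.exp(y)))
        assert fit.mu_max == pytest.approx(mu, rel=0.05)
        assert fit.lag == pytest.approx(lag_true, abs=0.5)
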