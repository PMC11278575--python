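"""4PL calibration fitting, inverse prediction and limit of blank."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucoloop.calibration import (
    CalibrationCurve,
    EstimateStatus,
    estimate_concentration,
    fit_calibration_curve,
    flag_nonmonotone_points,
    four_param_logistic,
    limit_of_blank,
)
from glucoloop.exceptions import (
    DataError,
    FitError,
    InsufficientDataError,
    StateError,
)
from glucoloop.traces import PANEL_CONCENTRATIONS_UM, CalibrationTable

TRUE_PARAMS = (0.0, 7.0, math.log10(900.0), 4.0)  # lower, upper, xmid, slope


def synthetic_table(params=TRUE_PARAMS, noise_sd=0.0, rng=None,
                    concs=PANEL_CONCENTRATIONS_UM):
    x = np.log10(np.asarray(concs, float))
    y = four_param_logistic(x, *params)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    blank = -9.9
    return CalibrationTable(
        sensor_id=9, blank_current=blank,
        responses={float(c): float(blank + d) for c, d in zip(concs, y)},
    )


class TestFitting:
    def test_noiseless_4pl_parameters_recovered(self):
        curve = fit_calibration_curve(synthetic_table())
        for fitted, true in zip(curve.params, TRUE_PARAMS):
            assert fitted == pytest.approx(true, rel=1e-6, abs=1e-6)

    def test_sensor2_fit_beats_flat_mean_model(self, tables, curves):
        concs = tables[2].concentrations
        deltas = tables[2].delta_array
        rss_fit = float(np.sum((deltas - curves[2].predict(concs)) ** 2))
        rss_flat = float(np.sum((deltas - deltas.mean()) ** 2))
        assert rss_fit < rss_flat

    def test_sensor1_saturating_curve_keeps_wide_monotone_range(self, curves):
        c1 = curves[1]
        assert c1.monotone_range[1] >= 1200.0
        assert -0.5 <= c1.params[0] <= 1.0  # lower asymptote, μA

    def test_asymptote_bias_under_noise_below_ten_percent(self):
        params = (1.0, 7.0, math.log10(200.0), 6.0)
        lowers, uppers = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            curve = fit_calibration_curve(
                synthetic_table(params, noise_sd=0.2, rng=rng),
                exclude_outlier=False,
            )
            lowers.append(curve.params[0])
            uppers.append(curve.params[1])
        assert abs(np.mean(lowers) - params[0]) / params[0] < 0.10
        assert abs(np.mean(uppers) - params[1]) / params[1] < 0.10

    def test_too_few_points_is_fit_error(self):
        with pytest.raises(FitError):
            fit_calibration_curve(synthetic_table(concs=(100, 400, 1600)))

    def test_degenerate_equal_responses_is_fit_error(self):
        tbl = CalibrationTable(
            sensor_id=9, blank_current=-9.9,
            responses={float(c): -3.0 for c in PANEL_CONCENTRATIONS_UM},
        )
        with pytest.raises(FitError):
            fit_calibration_curve(tbl)

    def test_sensor3_upturn_at_1600_flagged_and_excluded(self, tables, curves):
        # deltas rise 2.33 -> 3.56 between 1400 and 1600 μM: that point must
        # never be silently averaged into a monotone fit
        assert 1600.0 in flag_nonmonotone_points(tables[3])
        assert any(c == 1600.0 for c, _ in curves[3].excluded)

    def test_monotone_interpolant_model_round_trips(self, tables):
        curve = fit_calibration_curve(tables[2], model_kind="monotone_interpolant")
        lo, hi = curve.monotone_range
        for conc in np.geomspace(lo * 1.05, hi * 0.95, 5):
            est = estimate_concentration(curve, curve.predict(conc))
            assert est.value == pytest.approx(conc, rel=0.02)


class TestInversion:
    def test_round_trip_within_one_percent_across_monotone_range(self, curves):
        for curve in curves.values():
            lo, hi = curve.monotone_range
            for conc in np.geomspace(lo * 1.01, hi * 0.99, 20):
                est = estimate_concentration(curve, curve.predict(conc))
                assert est.status is EstimateStatus.OK
                assert est.value == pytest.approx(conc, rel=0.01)

    def test_800_uM_response_inverts_to_800(self, curves):
        est = estimate_concentration(curves[2], curves[2].predict(800.0))
        assert est.status is EstimateStatus.OK
        assert est.value == pytest.approx(800.0, rel=0.01)
        assert est.interval[0] <= est.value <= est.interval[1]

    def test_delta_above_maximum_response_flags_below_range(self, curves):
        curve = curves[2]
        est = estimate_concentration(curve, curve.predict(curve.monotone_range[0]) + 1.0)
        assert est.status is EstimateStatus.BELOW_RANGE
        assert est.value == pytest.approx(curve.monotone_range[0])

    def test_delta_at_lower_asymptote_flags_saturated(self, curves):
        curve = curves[2]
        est = estimate_concentration(curve, curve.params[0] - 0.5)
        assert est.status is EstimateStatus.SATURATED

    def test_unfitted_curve_is_state_error(self):
        bare = CalibrationCurve(
            sensor_id=1, model_kind="four_param_logistic", params=(),
            fit_range=(10.0, 1600.0), monotone_range=(10.0, 1600.0), fit_rss=0.0,
        )
        with pytest.raises(StateError):
            estimate_concentration(bare, 3.0)

    def test_strict_slope_gate_flags_flat_plateau_reading(self, curves):
        # at 300 μM the fixture sensors' response is ~flat; with a 0.5 μA per
        # decade usability gate the estimate must be flagged, not trusted
        curve = curves[2]
        est = estimate_concentration(curve, curve.predict(300.0), min_slope=0.5)
        assert est.status is not EstimateStatus.OK

    def test_median_inversion_error_under_noise(self):
        # 5% multiplicative noise on deltas; inversion across 600-1600 μM
        params = (0.0, 6.5, math.log10(1000.0), 5.0)
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.log10(np.asarray(PANEL_CONCENTRATIONS_UM, float))
            y = four_param_logistic(x, *params)
            noisy = y * (1.0 + rng.normal(0.0, 0.05, size=y.size))
            tbl = CalibrationTable(
                sensor_id=9, blank_current=-9.9,
                responses={float(c): float(-9.9 + d)
                           for c, d in zip(PANEL_CONCENTRATIONS_UM, noisy)},
            )
            try:
                curve = fit_calibration_curve(tbl, exclude_outlier=False)
            except FitError:
                continue
            for conc in (600, 800, 1000, 1200, 1400, 1600):
                truth = four_param_logistic(math.log10(conc), *params)
                est = estimate_concentration(curve, truth)
                if est.status is EstimateStatus.OK:
                    errors.append(abs(est.value - conc) / conc)
        assert np.median(errors) <= 0.15


class TestLimitOfBlank:
    def test_zero_blanks_give_zero_threshold(self):
        assert limit_of_blank([0.0, 0.0, 0.0]) == 0.0

    def test_hand_computed_example(self):
        # mean 0.05, sample SD sqrt(0.05/3) = 0.1290994...
        expected = 0.05 + 3.0 * math.sqrt(0.05 / 3.0)
        assert limit_of_blank([0.1, -0.1, 0.0, 0.2]) == pytest.approx(expected)

    @settings(derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=12))
    def test_threshold_never_below_mean(self, blanks):
        assert limit_of_blank(blanks) >= np.mean(blanks) - 1e-12

    def test_fewer_than_three_replicates_rejected(self):
        with pytest.raises(InsufficientDataError):
            limit_of_blank([0.1, 0.2])
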