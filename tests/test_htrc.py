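"""Thermal release-circuit twin: Joule heating, thermometry, control, release."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucoloop.exceptions import ConfigurationError, SafetyError
from glucoloop.htrc import (
    ControllerSpec,
    PatchSpec,
    ResistorNetwork,
    ThermalPlant,
    ThermalState,
    ThermistorParams,
    control_update,
    fit_thermistor_to_linear,
    joule_power,
    lm35_readout,
    plateau_temperature_c,
    release_step,
    simulate_htrc,
    steinhart_hart_temperature,
    step_plant,
    thermistor_resistance,
)


class TestJoulePower:
    def test_zero_duty_dissipates_nothing(self):
        per, total = joule_power(ResistorNetwork(), 0.0)
        assert per == total == 0.0

    def test_parallel_ladder_hand_arithmetic(self):
        per, total = joule_power(ResistorNetwork(), 1.0)
        assert per == pytest.approx(25.0 / 330.0)       # V^2/R per branch
        assert total == pytest.approx(9 * 25.0 / 330.0)  # ~0.682 W
        assert per < 0.5  # within the per-resistor rating

    def test_series_string_hand_arithmetic(self):
        net = ResistorNetwork(topology="series")
        _, total = joule_power(net, 1.0)
        assert total == pytest.approx(25.0 / (9 * 330.0))  # ~8.4 mW

    def test_rating_violation_raises_at_construction(self):
        with pytest.raises(SafetyError):
            ResistorNetwork(resistance_ohm=10.0)  # 2.5 W/branch > 0.5 W

    def test_clamp_keeps_per_resistor_power_within_rating(self):
        # a drifted resistance below spec would overload the parts; the
        # construction-time check cannot see it, the duty guard must
        net = ResistorNetwork()
        object.__setattr__(net, "resistance_ohm", 40.0)  # 0.625 W/branch
        per, _ = joule_power(net, 1.0, clamp=True)
        assert per <= net.power_rating_w + 1e-12
        with pytest.raises(SafetyError):
            joule_power(net, 1.0, clamp=False)


class TestThermometry:
    def test_degenerate_coefficients_give_constant_temperature(self):
        params = ThermistorParams(A=1 / 300.0, B=0.0, C=0.0)
        for r in (10.0, 1e4, 1e6):
            assert steinhart_hart_temperature(params, r) == pytest.approx(300.0)

    def test_standard_ntc_coefficients_near_room_temperature(self):
        params = ThermistorParams()
        # oracle: direct evaluation of 1/(A + B lnR + C (lnR)^3)
        ln_r = math.log(10_000.0)
        oracle = 1.0 / (params.A + params.B * ln_r + params.C * ln_r**3)
        t = steinhart_hart_temperature(params, 10_000.0)
        assert t == pytest.approx(oracle, rel=1e-12)
        assert 295.0 < t < 301.0  # ~298 K for a 10 kΩ NTC at its R25

    def test_temperature_strictly_decreases_with_resistance(self):
        params = ThermistorParams()
        rs = np.geomspace(100.0, 1e6, 200)
        temps = [steinhart_hart_temperature(params, r) for r in rs]
        assert all(b < a for a, b in zip(temps, temps[1:]))

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ConfigurationError):
            steinhart_hart_temperature(ThermistorParams(), 0.0)

    def test_lm35_zero_reads_zero(self):
        assert lm35_readout(0.0, 10, 5.0) == 0.0

    def test_lm35_quantization_within_one_quantum(self):
        quantum = 5.0 / 2**10 / 0.010  # ≈ 0.49 °C
        assert abs(lm35_readout(40.0, 10, 5.0) - 40.0) <= quantum

    def test_quantization_error_bounded_over_span(self):
        quantum = 5.0 / 2**12 / 0.010
        for t in np.linspace(0.0, 100.0, 101):
            assert abs(lm35_readout(t, 12, 5.0) - t) <= quantum

    def test_thermistor_and_linear_sensor_agree_when_cross_calibrated(self):
        params = fit_thermistor_to_linear(30.0, 45.0)
        for t in np.linspace(30.0, 45.0, 31):
            r = thermistor_resistance(t)
            via_sh = steinhart_hart_temperature(params, r) - 273.15
            via_lm35 = lm35_readout(t, adc_bits=16)
            assert abs(via_sh - via_lm35) < 0.5


class TestPlant:
    def test_equilibrium_at_ambient_with_heater_off(self):
        state = ThermalState(temperature_c=25.0)
        out = step_plant(state, ResistorNetwork(), 0.0, ThermalPlant(), 1.0)
        assert out.temperature_c == pytest.approx(25.0)

    def test_full_duty_converges_to_closed_form_steady_state(self):
        plant = ThermalPlant(c_th_j_per_c=5.0, tau_s=30.0)
        net = ResistorNetwork()
        expected = plant.steady_state_c(net.full_duty_power_w)
        state = ThermalState(temperature_c=plant.ambient_c)
        for _ in range(int(5 * plant.tau_s / 0.5)):
            state = step_plant(state, net, 1.0, plant, 0.5)
        assert state.temperature_c == pytest.approx(expected, abs=0.1)

    def test_step_size_refinement_changes_endpoint_little(self):
        def endpoint(dt):
            plant = ThermalPlant()
            state = ThermalState(temperature_c=plant.ambient_c)
            net = ResistorNetwork()
            for _ in range(int(600.0 / dt)):
                state = step_plant(state, net, 1.0, plant, dt)
            return state.temperature_c

        assert abs(endpoint(0.5) - endpoint(0.25)) < 0.05

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermalPlant(c_th_j_per_c=-1.0)
        with pytest.raises(ConfigurationError):
            step_plant(ThermalState(), ResistorNetwork(), 0.5, ThermalPlant(), 2.0)


class TestController:
    def test_cold_surface_demands_full_duty(self):
        assert control_update(40.0, 2.0, 25.0, 0.0) == 1.0

    def test_hot_surface_cuts_duty(self):
        assert control_update(40.0, 2.0, 41.0, 1.0) == 0.0

    def test_dead_band_holds_previous_duty(self):
        assert control_update(40.0, 2.0, 39.0, 1.0) == 1.0
        assert control_update(40.0, 2.0, 39.0, 0.0) == 0.0

    def test_closed_loop_never_exceeds_setpoint_plus_one(self):
        ts = simulate_htrc(duration_s=600.0, seed=0)
        assert ts["temp_C"].max() <= 40.0 + 1.0

    @pytest.mark.parametrize("tau", [30.0, 120.0, 300.0])
    @pytest.mark.parametrize("c_th", [5.0, 20.0, 50.0])
    def test_safety_envelope_across_plant_grid(self, tau, c_th):
        plant = ThermalPlant(c_th_j_per_c=c_th, tau_s=tau)
        net = ResistorNetwork()
        ts = simulate_htrc(duration_s=600.0, plant=plant, seed=1)
        assert ts["temp_C"].max() <= 41.0
        assert ts["temp_C"].min() >= plant.ambient_c - 0.5
        # where the 0.68 W heater can physically reach the band, it settles
        if plant.steady_state_c(net.full_duty_power_w) >= 41.0:
            assert 38.0 <= plateau_temperature_c(ts) <= 40.0

    def test_heater_power_equals_duty_times_ladder_power(self):
        ts = simulate_htrc(duration_s=120.0, seed=2)
        total_full = ResistorNetwork().full_duty_power_w
        np.testing.assert_allclose(ts["power_W"], ts["duty"] * total_full,
                                   atol=1e-12)


class TestRelease:
    def test_below_transition_window_nothing_releases(self):
        assert release_step(PatchSpec(), 30.0, 0.2, 10.0) == 0.2

    def test_full_activation_matches_first_order_closed_form(self):
        patch = PatchSpec()
        frac, t, dt = 0.0, 0.0, 1.0
        while t < 600.0:
            frac = release_step(patch, 41.0, frac, dt)
            t += dt
        expected = 1.0 - math.exp(-patch.release_rate_per_s * 600.0)
        assert frac == pytest.approx(expected, rel=1e-9)

    def test_activation_ramp_is_linear_inside_window(self):
        patch = PatchSpec()
        assert patch.activation(37.0) == 0.0
        assert patch.activation(38.5) == pytest.approx(0.5)
        assert patch.activation(40.0) == 1.0

    @settings(derandomize=True)
    @given(st.lists(st.floats(20.0, 45.0, allow_nan=False), min_size=1,
                    max_size=50))
    def test_release_fraction_never_decreases(self, temperatures):
        patch = PatchSpec()
        frac = 0.0
        for temp in temperatures:
            new = release_step(patch, temp, frac, 5.0)
            assert new >= frac
            assert 0.0 <= new <= 1.0
            frac = new
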