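"""Digital twin of the thermoresponsive drug-release circuit.

The release circuit Joule-heats a 9-element resistor ladder (330 Ω each,
½ W rated, parallel across a 5 V rail) under a gelatin patch loaded with
a hypoglycemic nanoemulsion. Gelatin at 2.5% w/v undergoes its
gel-to-sol transition at roughly 37-40 °C; holding the heated surface
near 40 °C lets the payload diffuse out. A temperature sensor (linear
LM35-style, 10 mV/°C, or an NTC thermistor read through the
Steinhart-Hart equation) closes the loop through a hysteresis (bang-bang)
controller.

The thermal plant is a lumped-capacitance first-order model:

    dT/dt = P(duty)/C_th - (T - T_ambient)/tau

with heat capacity C_th (J/°C) and a single loss time constant tau (s).
Defaults (C_th = 5 J/°C, tau = 110 s) place the full-duty steady state at
T_ambient + P*tau/C_th = 25 + 0.6818*110/5 = 40.0 °C, so an uncontrolled
heater plateaus right at the release window and the controller's job is
to hold it there without overshoot. Release follows first-order kinetics
gated by a linear thermal activation ramp across the transition window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SafetyError


# --------------------------------------------------------------------------
# electrical
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResistorNetwork:
    """Heater ladder: n identical resistors in parallel or series."""

    n_resistors: int = 9
    resistance_ohm: float = 330.0
    topology: str = "parallel"
    supply_voltage_v: float = 5.0
    power_rating_w: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_resistors, self.resistance_ohm,
               self.supply_voltage_v, self.power_rating_w) <= 0:
            raise ConfigurationError("network parameters must be positive")
        if self.topology not in ("parallel", "series"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        per, _ = _network_power(self)
        if per > self.power_rating_w:
            raise SafetyError(
                f"per-resistor dissipation {per:.3f} W exceeds "
                f"{self.power_rating_w} W rating at full duty"
            )

    @property
    def full_duty_power_w(self) -> float:
        return _network_power(self)[1]


def _network_power(net: ResistorNetwork) -> tuple[float, float]:
    v, r, n = net.supply_voltage_v, net.resistance_ohm, net.n_resistors
    if net.topology == "parallel":
        per = v * v / r           # each branch sees the full rail
        return per, n * per
    total = v * v / (n * r)       # series string: I = V/(nR), P_i = I^2 R
    return total / n, total


def joule_power(
    network: ResistorNetwork, duty: float, clamp: bool = True
) -> tuple[float, float]:
    """Dissipated power at a duty cycle: (per-resistor W, total W).

    Slow PWM at duty d scales the average power linearly: P = d * V^2/R
    per parallel branch (equivalently I^2 R). With ``clamp`` False a duty
    that would exceed the per-resistor rating raises ``SafetyError``;
    with the default clamp the duty is reduced to the rating limit.
    """
    if not 0 <= duty <= 1:
        raise ConfigurationError("duty must be within [0, 1]")
    per_full, total_full = _network_power(network)
    max_duty = min(network.power_rating_w / per_full, 1.0)
    if duty > max_duty:
        if not clamp:
            raise SafetyError(
                f"duty {duty} would dissipate {duty * per_full:.3f} W "
                f"per resistor, above the {network.power_rating_w} W rating"
            )
        duty = max_duty
    return duty * per_full, duty * total_full


# --------------------------------------------------------------------------
# thermometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermistorParams:
    """Steinhart-Hart coefficients (units 1/K): 1/T = A + B ln R + C (ln R)^3."""

    A: float = 1.129148e-3
    B: float = 2.34125e-4
    C: float = 8.76741e-8


def steinhart_hart_temperature(params: ThermistorParams, resistance_ohm: float) -> float:
    """Absolute temperature (K) of an NTC thermistor from its resistance."""
    if resistance_ohm <= 0:
        raise ConfigurationError("thermistor resistance must be > 0 Ω")
    ln_r = math.log(resistance_ohm)
    inv_t = params.A + params.B * ln_r + params.C * ln_r**3
    if inv_t <= 0:
        raise ConfigurationError(
            "Steinhart-Hart denominator non-positive for this resistance"
        )
    return 1.0 / inv_t


def lm35_readout(
    true_temperature_c: float, adc_bits: int = 10, v_ref: float = 5.0
) -> float:
    """Linear-sensor temperature readout through an ADC.

    The sensor outputs 10 mV/°C over a [0, 100] °C span; the voltage is
    quantized by an ``adc_bits`` converter referenced to ``v_ref`` and
    converted back to °C. Out-of-span temperatures are clamped, so the
    measurement error is bounded by one quantum, v_ref / 2**bits / 0.010 °C.
    """
    if adc_bits < 1 or v_ref <= 0:
        raise ConfigurationError("adc_bits >= 1 and v_ref > 0 required")
    t = min(max(true_temperature_c, 0.0), 100.0)
    volts = 0.010 * t
    code = round(volts / v_ref * (2**adc_bits))
    code = min(max(code, 0), 2**adc_bits - 1)
    return code * v_ref / (2**adc_bits) / 0.010


def fit_thermistor_to_linear(
    lo_c: float = 30.0, hi_c: float = 45.0, r25_ohm: float = 10000.0,
    beta: float = 3950.0,
) -> ThermistorParams:
    """Steinhart-Hart coefficients matching a beta-model NTC over a span.

    Convenience for the cross-sensor consistency check: generates
    (R, T) pairs from a standard beta-parameter NTC model and solves the
    linear system for A, B, C at three temperatures across [lo, hi] °C.
    """
    temps_k = np.array([lo_c, (lo_c + hi_c) / 2, hi_c]) + 273.15
    r = r25_ohm * np.exp(beta * (1 / temps_k - 1 / 298.15))
    ln_r = np.log(r)
    m = np.column_stack([np.ones(3), ln_r, ln_r**3])
    a, b, c = np.linalg.solve(m, 1 / temps_k)
    return ThermistorParams(A=float(a), B=float(b), C=float(c))


def thermistor_resistance(
    temperature_c: float, r25_ohm: float = 10000.0, beta: float = 3950.0
) -> float:
    """Beta-model NTC resistance at a temperature (inverse of the readout path)."""
    t_k = temperature_c + 273.15
    return r25_ohm * math.exp(beta * (1 / t_k - 1 / 298.15))


# --------------------------------------------------------------------------
# thermal plant, controller, release
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalPlant:
    """Lumped-capacitance plant: heat capacity and loss time constant."""

    c_th_j_per_c: float = 5.0
    tau_s: float = 110.0
    ambient_c: float = 25.0

    def __post_init__(self) -> None:
        if self.c_th_j_per_c <= 0 or self.tau_s <= 0:
            raise ConfigurationError("C_th and tau must be > 0")

    def steady_state_c(self, power_w: float) -> float:
        """Equilibrium temperature under constant heating power."""
        return self.ambient_c + power_w * self.tau_s / self.c_th_j_per_c


@dataclass(frozen=True)
class PatchSpec:
    """Gelatin patch array and its thermal-release parameters."""

    n_patches: int = 5
    area_cm2: float = 1.0
    gelatin_pct: float = 2.5
    transition_low_c: float = 37.0
    transition_high_c: float = 40.0
    release_rate_per_s: float = 1.0 / 600.0

    def __post_init__(self) -> None:
        if self.transition_low_c >= self.transition_high_c:
            raise ConfigurationError("transition window must have T_low < T_high")
        if self.release_rate_per_s < 0:
            raise ConfigurationError("release rate must be >= 0")

    def activation(self, temperature_c: float) -> float:
        """Thermal activation: 0 below the window, linear ramp inside, 1 above."""
        lo, hi = self.transition_low_c, self.transition_high_c
        return float(np.clip((temperature_c - lo) / (hi - lo), 0.0, 1.0))


@dataclass(frozen=True)
class ThermalState:
    """Snapshot of the heated surface and the cumulative payload release."""

    time_s: float = 0.0
    temperature_c: float = 25.0
    duty: float = 0.0
    heater_power_w: float = 0.0
    release_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.duty <= 1:
            raise ConfigurationError("duty must be within [0, 1]")
        if not 0 <= self.release_fraction <= 1:
            raise ConfigurationError("release_fraction must be within [0, 1]")
        if not math.isfinite(self.temperature_c):
            raise ConfigurationError("temperature must be finite")


def step_plant(
    state: ThermalState,
    network: ResistorNetwork,
    duty: float,
    plant: ThermalPlant,
    dt_s: float,
) -> ThermalState:
    """Advance the lumped thermal model one explicit-Euler step.

    T <- T + dt * (P/C_th - (T - ambient)/tau). Requires dt <= 1 s for
    accuracy of the explicit update at the default time constants.
    """
    if not 0 < dt_s <= 1.0:
        raise ConfigurationError("dt must be in (0, 1] s")
    per_w, total_w = joule_power(network, duty)
    dT = dt_s * (total_w / plant.c_th_j_per_c
                 - (state.temperature_c - plant.ambient_c) / plant.tau_s)
    return replace(
        state,
        time_s=state.time_s + dt_s,
        temperature_c=state.temperature_c + dT,
        duty=duty,
        heater_power_w=total_w,
    )


def control_update(
    setpoint_c: float, band_c: float, measured_c: float, duty: float
) -> float:
    """Hysteresis (bang-bang) law holding the surface near the setpoint.

    Full duty below ``setpoint - band``, heater off above ``setpoint``,
    duty unchanged inside the dead band — the band prevents chatter at
    the boundary and matches the gelatin transition window when
    setpoint=40 and band=2 (on below 38 °C, off above 40 °C).
    """
    if band_c <= 0:
        raise ConfigurationError("hysteresis band must be > 0")
    if measured_c < setpoint_c - band_c:
        return 1.0
    if measured_c > setpoint_c:
        return 0.0
    return duty


def release_step(
    patch: PatchSpec, temperature_c: float, release_fraction: float, dt_s: float
) -> float:
    """First-order release gated by thermal activation; never decreases.

    fraction <- 1 - (1 - fraction) * exp(-a(T) * k * dt) where a(T) is the
    linear activation ramp across the gelatin transition window.
    """
    if not 0 <= release_fraction <= 1:
        raise ConfigurationError("release_fraction must be within [0, 1]")
    a = patch.activation(temperature_c)
    # expm1 keeps the update exactly zero at zero activation
    gained = (1.0 - release_fraction) * (-math.expm1(-a * patch.release_rate_per_s * dt_s))
    return release_fraction + gained


@dataclass(frozen=True)
class ControllerSpec:
    """Hysteresis controller and measurement-path configuration."""

    setpoint_c: float = 40.0
    band_c: float = 0.5
    period_s: float = 1.0
    sensor: str = "lm35"            # or "thermistor"
    adc_bits: int = 12
    v_ref: float = 5.0
    noise_sd_c: float = 0.1

    def __post_init__(self) -> None:
        if self.band_c <= 0 or self.period_s <= 0:
            raise ConfigurationError("band and control period must be > 0")
        if self.sensor not in ("lm35", "thermistor"):
            raise ConfigurationError(f"unknown sensor {self.sensor!r}")


def simulate_htrc(
    duration_s: float = 600.0,
    network: ResistorNetwork | None = None,
    plant: ThermalPlant | None = None,
    patch: PatchSpec | None = None,
    controller: ControllerSpec | None = None,
    dt_s: float = 0.5,
    seed: int | None = None,
    initial_temperature_c: float | None = None,
) -> pd.DataFrame:
    """Run the closed thermal loop and return its time series.

    Each control period the surface temperature is measured (sensor model
    plus Gaussian noise and ADC quantization), the hysteresis law updates
    the duty, and the plant and release kinetics advance at ``dt_s``.
    Columns: time_s, temp_C, measured_C, duty, power_W, release_fraction.
    Deterministic for a fixed seed.
    """
    network = network or ResistorNetwork()
    plant = plant or ThermalPlant()
    patch = patch or PatchSpec()
    controller = controller or ControllerSpec()
    rng = np.random.default_rng(seed)

    t0 = plant.ambient_c if initial_temperature_c is None else initial_temperature_c
    state = ThermalState(time_s=0.0, temperature_c=t0)
    duty = 0.0
    release = 0.0
    thermistor_cal = (
        fit_thermistor_to_linear() if controller.sensor == "thermistor" else None
    )

    rows = []
    next_control = 0.0
    measured = t0
    n_steps = int(round(duration_s / dt_s))
    for _ in range(n_steps):
        if state.time_s >= next_control - 1e-9:
            noisy = state.temperature_c + rng.normal(0.0, controller.noise_sd_c)
            if controller.sensor == "lm35":
                measured = lm35_readout(noisy, controller.adc_bits, controller.v_ref)
            else:
                r = thermistor_resistance(noisy)
                measured = steinhart_hart_temperature(thermistor_cal, r) - 273.15
            duty = control_update(
                controller.setpoint_c, controller.band_c, measured, duty
            )
            next_control += controller.period_s
        state = step_plant(state, network, duty, plant, dt_s)
        release = release_step(patch, state.temperature_c, release, dt_s)
        rows.append(
            (state.time_s, state.temperature_c, measured, duty,
             state.heater_power_w, release)
        )
    return pd.DataFrame(
        rows,
        columns=["time_s", "temp_C", "measured_C", "duty", "power_W",
                 "release_fraction"],
    )


def plateau_temperature_c(
    timeseries: pd.DataFrame, window_s: float = 120.0
) -> float:
    """Mean surface temperature over the final ``window_s`` of a run."""
    t_end = timeseries["time_s"].iloc[-1]
    tail = timeseries[timeseries["time_s"] > t_end - window_s]
    return float(tail["temp_C"].mean())
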