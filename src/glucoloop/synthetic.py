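"""Seeded synthetic-data generators: CA traces, sensor panels, sweat
scenarios and OGTT cohorts.

Every generator is a pure function of its spec and seed, so fixtures are
reproducible byte-for-byte without hardware or downloads.

Chronoamperometric traces are modelled as a diffusion-controlled
(Cottrell-like) transient decaying onto a concentration-dependent plateau:

    i(t) = plateau + A / sqrt(t + t0) * exp(-t / tau_tr) + N(0, sd)

The 1/sqrt(t) term emulates the diffusion-limited early current; the
exponential cutoff (default 2 s) makes the transient negligible by the
endpoint window so that noiseless endpoint extraction recovers the
plateau. Plateau currents default to the packaged per-sensor calibration
fixture, so a zero-noise panel reproduces the printed table exactly.

OGTT cohorts draw per-subject Gaussian profiles around group time-curves
whose 0 h and 1 h values are the reported group means/SDs; the unreported
2 h and 3 h values return linearly toward baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .ogtt import OGTTRecord
from .traces import (
    CATrace,
    CalibrationTable,
    CURRENT_RANGE_UA,
    DEFAULT_DURATION_S,
    PANEL_CONCENTRATIONS_UM,
    build_calibration_table,
)

#: Regularizer avoiding the 1/sqrt(t) singularity at t = 0, s.
T0_REGULARIZER_S: float = 0.1

#: Default additive current noise, μA.
DEFAULT_NOISE_SD_UA: float = 0.05


@dataclass(frozen=True)
class TraceGeneratorSpec:
    """Parameters of one synthetic CA trace."""

    sensor_id: int = 1
    concentration_um: float | None = None
    plateau_current_ua: float = -9.98
    transient_amplitude_ua: float = -1.0
    transient_timescale_s: float = 2.0
    noise_sd_ua: float = DEFAULT_NOISE_SD_UA
    duration_s: float = DEFAULT_DURATION_S
    sample_rate_hz: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_ua < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ConfigurationError("duration and sample rate must be > 0")
        if self.transient_timescale_s <= 0:
            raise ConfigurationError("transient timescale must be > 0")


def generate_trace(spec: TraceGeneratorSpec) -> CATrace:
    """Synthesize one seeded CA trace from its generator spec.

    Currents are clipped to the potentiostat's ±10 μA range (instrument
    saturation), which only affects the early transient, never the
    endpoint window.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz
    i = (
        spec.plateau_current_ua
        + spec.transient_amplitude_ua
        / np.sqrt(t + T0_REGULARIZER_S)
        * np.exp(-t / spec.transient_timescale_s)
    )
    if spec.noise_sd_ua > 0:
        i = i + rng.normal(0.0, spec.noise_sd_ua, size=n)
    i = np.clip(i, *CURRENT_RANGE_UA)
    return CATrace(
        sensor_id=spec.sensor_id,
        concentration_um=spec.concentration_um,
        times_s=t,
        currents_ua=i,
    )


def generate_panel(
    sensor_id: int,
    seed: int | None = None,
    noise_sd_ua: float = DEFAULT_NOISE_SD_UA,
    response_profile: Mapping[float | None, float] | None = None,
    tail_fraction: float = 0.1,
) -> CalibrationTable:
    """Generate traces for blank + full panel and assemble a calibration table.

    ``response_profile`` maps concentration (``None`` for the blank) to
    the plateau current; by default it is the packaged fixture row for
    the sensor, so with ``noise_sd_ua=0`` the assembled table reproduces
    the printed calibration data to within 0.01 μA.
    """
    if response_profile is None:
        from .fixtures import load_fixture_tables  # deferred: avoids cycle

        tables = load_fixture_tables()
        if sensor_id not in tables:
            raise ConfigurationError(
                f"no packaged profile for sensor {sensor_id}; "
                "pass response_profile explicitly"
            )
        tbl = tables[sensor_id]
        response_profile = {None: tbl.blank_current, **tbl.responses}
    if not response_profile:
        raise ConfigurationError("empty response profile")

    rng = np.random.default_rng(seed)
    traces = []
    for conc, plateau in sorted(
        response_profile.items(), key=lambda kv: -1.0 if kv[0] is None else kv[0]
    ):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traces.append(
            generate_trace(
                TraceGeneratorSpec(
                    sensor_id=sensor_id,
                    concentration_um=conc,
                    plateau_current_ua=plateau,
                    noise_sd_ua=noise_sd_ua,
                    seed=sub_seed,
                )
            )
        )
    return build_calibration_table(
        sensor_id, traces=traces, tail_fraction=tail_fraction,
        provenance=[f"synthetic panel, seed={seed}, noise_sd={noise_sd_ua}"],
    )


# --------------------------------------------------------------------------
# sweat-glucose scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SweatScenario:
    """Piecewise-linear true sweat-glucose time course for loop runs.

    ``timeline`` is a sequence of (time s, concentration μM) breakpoints;
    the loop samples it every ``sampling_period_s`` and perturbs the
    sensor response with Gaussian noise of ``response_noise_sd_ua`` μA.
    """

    timeline: tuple[tuple[float, float], ...]
    sampling_period_s: float = 60.0
    response_noise_sd_ua: float = DEFAULT_NOISE_SD_UA

    def __post_init__(self) -> None:
        times = [p[0] for p in self.timeline]
        concs = [p[1] for p in self.timeline]
        if len(times) < 1 or any(np.diff(times) <= 0):
            raise ConfigurationError("timeline times must be strictly increasing")
        if any(c < 0 for c in concs):
            raise ConfigurationError("concentrations must be >= 0")
        if self.sampling_period_s <= 0:
            raise ConfigurationError("sampling period must be > 0")

    @property
    def duration_s(self) -> float:
        return self.timeline[-1][0]

    def concentration_at(self, time_s: float) -> float:
        t = np.array([p[0] for p in self.timeline])
        c = np.array([p[1] for p in self.timeline])
        return float(np.interp(time_s, t, c))

    @staticmethod
    def constant(concentration_um: float, duration_s: float = 3600.0,
                 **kw) -> "SweatScenario":
        return SweatScenario(
            timeline=((0.0, concentration_um), (duration_s, concentration_um)), **kw
        )


# --------------------------------------------------------------------------
# OGTT cohorts
# --------------------------------------------------------------------------

#: Reported group means ± SD (mg/dL) at 0 h and 1 h; 2 h and 3 h values are
#: not reported and default to a linear return toward baseline.
DEFAULT_OGTT_PROFILES: dict[str, dict[str, tuple[float, ...]]] = {
    "control": {
        "mean": (188.0, 340.0, 264.0, 188.0),
        "sd": (46.0, 100.0, 73.0, 46.0),
    },
    "sitagliptin": {
        "mean": (163.0, 305.0, 234.0, 163.0),
        "sd": (25.0, 60.0, 42.5, 25.0),
    },
    "dapagliflozin": {
        "mean": (183.0, 207.0, 195.0, 183.0),
        "sd": (50.0, 36.0, 43.0, 50.0),
    },
}

OGTT_TIMES_H: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

#: Physiological floor applied to Gaussian draws, mg/dL.
GLUCOSE_FLOOR_MGDL: float = 40.0


def generate_ogtt_cohort(
    n_per_group: int = 10,
    seed: int | None = None,
    profiles: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    times_h: Sequence[float] = OGTT_TIMES_H,
) -> list[OGTTRecord]:
    """Draw a seeded cohort of per-subject Gaussian OGTT profiles.

    Each subject's glucose at each time is an independent normal draw
    around the group profile, truncated below at 40 mg/dL.
    """
    if n_per_group < 2:
        raise ConfigurationError("need n >= 2 subjects per group")
    profiles = profiles or DEFAULT_OGTT_PROFILES
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(profiles):
        prof = profiles[group]
        mean = np.asarray(prof["mean"], float)
        sd = np.asarray(prof["sd"], float)
        if mean.size != len(times_h) or sd.size != len(times_h):
            raise ConfigurationError("profile length must match the time grid")
        if np.any(sd < 0):
            raise ConfigurationError("SDs must be >= 0")
        for k in range(n_per_group):
            g = rng.normal(mean, sd)
            g = np.maximum(g, GLUCOSE_FLOOR_MGDL)
            records.append(
                OGTTRecord(
                    subject_id=f"{group}-{k + 1:03d}",
                    group=group if group in ("control", "sitagliptin",
                                             "dapagliflozin") else "other",
                    times_h=tuple(float(t) for t in times_h),
                    glucose_mgdl=tuple(float(v) for v in g),
                )
            )
    return records
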