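"""End-to-end closed loop: sense -> estimate -> decide -> heat & release.

``run_closed_loop`` drives the whole simulated device over a sweat-glucose
scenario: at each sampling instant the sensing side produces a noisy
blank-subtracted response from the true concentration through the fitted
calibration curve, the inverse prediction estimates the concentration,
the decision engine compares it with the therapy threshold, and the first
TRIGGER starts the thermal release simulation. Outputs are an ordered
JSON-lines event log and (when triggered) the thermal time series. The
whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .calibration import CalibrationCurve, estimate_concentration, fit_calibration_curve
from .decision import Action, DecisionPolicy, LoopState, decide, write_event_log
from .exceptions import ConfigurationError
from .fixtures import load_fixture_tables
from .htrc import (
    ControllerSpec,
    PatchSpec,
    ResistorNetwork,
    ThermalPlant,
    plateau_temperature_c,
    simulate_htrc,
)
from .synthetic import SweatScenario, TraceGeneratorSpec, generate_trace
from .traces import extract_endpoint_current


class ScenarioConfig(BaseModel):
    """YAML-loadable sweat scenario: breakpoints, sampling, noise."""

    timeline: list[tuple[float, float]]
    sampling_period_s: float = 60.0
    response_noise_sd_ua: float = 0.05

    def to_scenario(self) -> SweatScenario:
        return SweatScenario(
            timeline=tuple((float(t), float(c)) for t, c in self.timeline),
            sampling_period_s=self.sampling_period_s,
            response_noise_sd_ua=self.response_noise_sd_ua,
        )


class RunConfig(BaseModel):
    """Full closed-loop run configuration."""

    sensor_id: int = 2
    scenario: ScenarioConfig
    threshold_um: float = 400.0
    cooldown_s: float = 1800.0
    require_status_ok: bool = True
    htrc_duration_s: float = 600.0
    #: minimum local calibration slope (μA per decade) for a reading to be
    #: acted upon; flat-plateau readings below it are flagged, not trusted
    min_usable_slope: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        return cls.model_validate(yaml.safe_load(p.read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class LoopResult:
    """Everything a closed-loop run produced."""

    events: list[dict[str, Any]]
    state: LoopState
    curve: CalibrationCurve
    thermal: pd.DataFrame | None = None
    config_hash: str = ""
    seed: int = 0

    @property
    def n_triggers(self) -> int:
        return sum(1 for e in self.events if e["kind"] == "command")

    @property
    def plateau_c(self) -> float | None:
        if self.thermal is None:
            return None
        return plateau_temperature_c(self.thermal)


def run_closed_loop(
    config: RunConfig,
    curve: CalibrationCurve | None = None,
    network: ResistorNetwork | None = None,
    plant: ThermalPlant | None = None,
    patch: PatchSpec | None = None,
    controller: ControllerSpec | None = None,
) -> LoopResult:
    """Execute the full loop over the configured scenario.

    The calibration curve defaults to a 4PL fit of the packaged table for
    ``config.sensor_id``. Sensing runs through the real chain: a
    synthetic 30 s CA trace is generated whose plateau is the blank plus
    the curve's response at the true concentration, with Gaussian current
    noise; the endpoint is extracted and blank-subtracted before inverse
    prediction, so response noise is averaged down by the endpoint window
    exactly as for a measured trace. The thermal simulation runs once per
    TRIGGER with a seed derived from the run seed.
    """
    tables = load_fixture_tables()
    if config.sensor_id not in tables:
        raise ConfigurationError(f"unknown sensor {config.sensor_id}")
    blank_ua = tables[config.sensor_id].blank_current
    if curve is None:
        curve = fit_calibration_curve(tables[config.sensor_id])

    scenario = config.scenario.to_scenario()
    policy = DecisionPolicy(
        threshold_um=config.threshold_um,
        cooldown_s=config.cooldown_s,
        require_status_ok=config.require_status_ok,
    )
    rng = np.random.default_rng(config.seed)
    state = LoopState()
    state.log(0.0, "htrc_status", armed=True, config_hash=config.config_hash(),
              seed=config.seed)

    thermal: pd.DataFrame | None = None
    times = np.arange(0.0, scenario.duration_s + 1e-9, scenario.sampling_period_s)
    for t in times:
        true_c = scenario.concentration_at(float(t))
        resp = curve.predict(max(true_c, curve.fit_range[0] * 0.5))
        trace = generate_trace(
            TraceGeneratorSpec(
                sensor_id=config.sensor_id,
                concentration_um=true_c,
                plateau_current_ua=blank_ua + resp,
                noise_sd_ua=scenario.response_noise_sd_ua,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        delta = extract_endpoint_current(trace) - blank_ua
        estimate = estimate_concentration(
            curve, delta, min_slope=config.min_usable_slope
        )
        decide(policy, estimate, state, time_s=float(t))
        if state.action is Action.TRIGGER and thermal is None:
            htrc_seed = int(rng.integers(0, 2**31 - 1))
            thermal = simulate_htrc(
                duration_s=config.htrc_duration_s,
                network=network, plant=plant, patch=patch,
                controller=controller, seed=htrc_seed,
            )
            state.log(
                float(t), "htrc_status",
                plateau_C=round(plateau_temperature_c(thermal), 2),
                release_fraction=round(
                    float(thermal["release_fraction"].iloc[-1]), 4
                ),
                htrc_seed=htrc_seed,
            )
    return LoopResult(
        events=state.event_log, state=state, curve=curve, thermal=thermal,
        config_hash=config.config_hash(), seed=config.seed,
    )


def write_loop_outputs(result: LoopResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the event log (JSON lines) and thermal time series (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"events": out / "events.jsonl"}
    write_event_log(result.events, paths["events"])
    if result.thermal is not None:
        paths["thermal"] = out / "thermal.csv"
        result.thermal.to_csv(paths["thermal"], index=False)
    return paths
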