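"""Chronoamperometric trace handling.

A chronoamperometric (CA) recording applies a potential step to the working
electrode and records current versus time; the current decays as analyte
diffusion to the electrode becomes rate-limiting and settles toward a
quasi-steady plateau. This module reduces a 30 s CA trace to a single
endpoint current, subtracts the blank (no-analyte) baseline, and assembles
per-sensor calibration tables mapping glucose concentration to
blank-subtracted response.

Currents are in microamperes (μA), matching the ±10 μA potentiostat range;
concentrations are in micromolar (μM) glucose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, InvalidTraceError

#: Glucose concentration panel (μM) used for sensor characterisation.
PANEL_CONCENTRATIONS_UM: tuple[float, ...] = (
    10, 50, 100, 200, 400, 600, 800, 1000, 1200, 1400, 1600,
)

#: Potentiostat measurement range, μA.
CURRENT_RANGE_UA: tuple[float, float] = (-10.0, 10.0)

#: Nominal recording length, s.
DEFAULT_DURATION_S: float = 30.0

#: Fraction of the trace tail averaged into the endpoint current.
DEFAULT_TAIL_FRACTION: float = 0.1


@dataclass(frozen=True)
class CATrace:
    """One chronoamperometric recording.

    Parameters
    ----------
    sensor_id : int
        Identifier of the biosensor (small positive integer).
    concentration_um : float or None
        Nominal glucose concentration in μM; ``None`` marks the blank
        control (analyte-free matrix).
    times_s : numpy.ndarray
        Sample times in seconds, strictly increasing, starting at 0.
    currents_ua : numpy.ndarray
        Sampled currents in μA, finite, within the potentiostat range.
    """

    sensor_id: int
    concentration_um: float | None
    times_s: np.ndarray
    currents_ua: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        i = np.asarray(self.currents_ua, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "currents_ua", i)
        if t.ndim != 1 or i.ndim != 1 or t.size != i.size:
            raise InvalidTraceError("times and currents must be 1-D and equal length")
        if t.size < 2:
            raise InvalidTraceError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(i)):
            raise DataError("trace contains non-finite samples")
        if t[0] < 0 or not np.all(np.diff(t) > 0):
            raise InvalidTraceError("times must be strictly increasing and start at >= 0")
        lo, hi = CURRENT_RANGE_UA
        if i.min() < lo - 1e-9 or i.max() > hi + 1e-9:
            raise InvalidTraceError(
                f"currents outside potentiostat range [{lo}, {hi}] μA"
            )
        if self.sensor_id is not None and self.sensor_id < 1:
            raise InvalidTraceError("sensor_id must be a positive integer")
        if self.concentration_um is not None and self.concentration_um < 0:
            raise InvalidTraceError("concentration must be >= 0 μM")

    @property
    def is_blank(self) -> bool:
        return self.concentration_um is None or self.concentration_um == 0

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


def extract_endpoint_current(
    trace: CATrace, tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> float:
    """Reduce a CA trace to its endpoint current.

    The endpoint is the time-weighted mean current over the final
    ``tail_fraction`` of the recording's time span (trapezoidal average),
    which is robust to the early diffusion transient and insensitive to
    the sampling grid for noiseless signals.

    Returns the endpoint current in μA.
    """
    if not 0 < tail_fraction <= 1:
        raise InvalidTraceError("tail_fraction must be in (0, 1]")
    t = trace.times_s
    i = trace.currents_ua
    t_start = t[-1] - tail_fraction * (t[-1] - t[0])
    # integrate the piecewise-linear interpolant over exactly [t_start, t_end]
    # so the result does not depend on whether a sample lands on the boundary
    inside = t > t_start
    tt = np.concatenate(([t_start], t[inside]))
    ii = np.concatenate(([np.interp(t_start, t, i)], i[inside]))
    span = tt[-1] - tt[0]
    if span == 0:
        return float(ii[-1])
    return float(np.trapezoid(ii, tt) / span)


def blank_subtract(response_ua: float, blank_ua: float) -> float:
    """Blank-subtracted response: analyte signal isolated from baseline.

    ``delta = response - blank``; the blank is the current of the
    analyte-free matrix measured on the same sensor.
    """
    if not (math.isfinite(response_ua) and math.isfinite(blank_ua)):
        raise DataError("blank_subtract requires finite currents")
    return response_ua - blank_ua


@dataclass
class CalibrationTable:
    """Per-sensor endpoint currents across the concentration panel.

    ``responses`` maps concentration (μM) to raw endpoint current (μA);
    ``deltas`` holds the blank-subtracted responses, computed on
    construction so that ``deltas[c] == responses[c] - blank_current``
    exactly.
    """

    sensor_id: int
    blank_current: float
    responses: dict[float, float]
    deltas: dict[float, float] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.blank_current):
            raise DataError("blank current must be finite")
        concs = list(self.responses)
        if len(set(concs)) != len(concs):
            raise DataError("duplicate concentrations in panel")
        for c, r in self.responses.items():
            if c <= 0:
                raise DataError("panel concentrations must be > 0 μM")
            if not math.isfinite(r):
                raise DataError(f"non-finite response at {c} μM")
        self.deltas = {
            c: blank_subtract(r, self.blank_current)
            for c, r in sorted(self.responses.items())
        }

    @property
    def concentrations(self) -> np.ndarray:
        return np.array(sorted(self.responses), dtype=float)

    @property
    def delta_array(self) -> np.ndarray:
        return np.array([self.deltas[c] for c in sorted(self.deltas)], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        concs = sorted(self.responses)
        return pd.DataFrame(
            {
                "sensor_id": self.sensor_id,
                "concentration_uM": concs,
                "current_uA": [self.responses[c] for c in concs],
                "delta_uA": [self.deltas[c] for c in concs],
            }
        )


def build_calibration_table(
    sensor_id: int,
    endpoints: Mapping[float | None, float] | None = None,
    traces: Iterable[CATrace] | None = None,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    provenance: Sequence[str] = (),
) -> CalibrationTable:
    """Assemble a calibration table from endpoint currents or raw traces.

    Exactly one blank entry must be present: key ``None`` (or 0) in
    ``endpoints``, or a trace whose concentration marks it as blank.
    Blank-subtracted deltas are populated for every non-blank panel
    concentration.
    """
    if (endpoints is None) == (traces is None):
        raise ConfigurationError("provide exactly one of endpoints or traces")
    if traces is not None:
        endpoints = {}
        for tr in traces:
            key = None if tr.is_blank else float(tr.concentration_um)
            if key in endpoints:
                raise DataError(f"duplicate panel entry for concentration {key}")
            endpoints[key] = extract_endpoint_current(tr, tail_fraction)

    blank_keys = [k for k in endpoints if k is None or k == 0]
    if len(blank_keys) != 1:
        raise ConfigurationError(
            f"exactly one blank entry required, found {len(blank_keys)}"
        )
    blank = float(endpoints[blank_keys[0]])
    responses = {
        float(c): float(i) for c, i in endpoints.items() if c not in blank_keys
    }
    if not responses:
        raise ConfigurationError("panel has no non-blank concentrations")
    return CalibrationTable(
        sensor_id=sensor_id,
        blank_current=blank,
        responses=responses,
        provenance=list(provenance),
    )


def read_trace_csv(path: str | Path, sensor_id: int = 1,
                   concentration_um: float | None = None) -> CATrace:
    """Read a two-column trace file (header ``time_s,current_uA``, '#' comments)."""
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "current_uA"} - set(df.columns)
    if missing:
        raise DataError(f"trace file missing columns: {sorted(missing)}")
    return CATrace(
        sensor_id=sensor_id,
        concentration_um=concentration_um,
        times_s=df["time_s"].to_numpy(float),
        currents_ua=df["current_uA"].to_numpy(float),
    )


def write_trace_csv(trace: CATrace, path: str | Path) -> None:
    """Write a trace in the two-column dialect read by :func:`read_trace_csv`."""
    with open(path, "w") as fh:
        fh.write(f"# sensor_id: {trace.sensor_id}\n")
        conc = "" if trace.concentration_um is None else trace.concentration_um
        fh.write(f"# concentration_uM: {conc}\n")
        fh.write("time_s,current_uA\n")
        for t, i in zip(trace.times_s, trace.currents_ua):
            fh.write(f"{t:.6g},{i:.6g}\n")
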