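"""Packaged calibration fixtures for the five characterised biosensors.

Two CSVs ship with the package: the raw chronoamperometric endpoint
currents for blank + 11 glucose concentrations per sensor, and the
blank-subtracted calibration responses derived from them (printed at two
decimals). Both are checksummed at load time. Two cells were corrected
relative to the printed source and carry provenance flags: the sensor-3
response at 50 μM is stored sign-corrected as −3.00 μA (the printed raw
value is inconsistent with its own blank-subtracted response, which
requires −3.00 − (−9.98) = 6.98), and a duplicated "100 μM" column header
is read as 1000 μM to match the derived table.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .exceptions import IntegrityError
from .traces import CalibrationTable, build_calibration_table

_CHECKSUMS = {
    "table1.csv": "40407ca2109831657a2de40b87e6f99cce451187fe8f46475eb5264c047ec527",
    "table2.csv": "8436699078738430f6a8ea279ee6c18ed89748fb46a1585a391d4c0dbcdb2f48",
}

#: Provenance flags attached to the affected sensors' tables.
PROVENANCE_FLAGS = {
    3: ["sign-corrected: 50 μM response stored as -3.00 μA for arithmetic "
        "consistency with its blank-subtracted value (6.98)"],
    "header": "duplicated '100 μM' column header read as 1000 μM",
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("glucoloop") / "data" / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise IntegrityError(
            f"fixture {name} failed checksum verification "
            f"(got {digest[:12]}..., expected {_CHECKSUMS[name][:12]}...)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), comment="#")


def load_fixture_tables() -> dict[int, CalibrationTable]:
    """Load the packaged endpoint currents as per-sensor calibration tables.

    Returns tables for sensors 1-5 with blank-subtracted deltas computed
    from the raw currents. Corrected cells carry provenance flags.
    """
    df = _read_fixture("table1.csv")
    tables: dict[int, CalibrationTable] = {}
    for sid, sub in df.groupby("sensor_id"):
        endpoints = {}
        for _, row in sub.iterrows():
            key = None if row["is_blank"] == 1 else float(row["concentration_uM"])
            endpoints[key] = float(row["current_uA"])
        prov = [PROVENANCE_FLAGS["header"]]
        prov += PROVENANCE_FLAGS.get(int(sid), [])
        tables[int(sid)] = build_calibration_table(
            int(sid), endpoints=endpoints, provenance=prov
        )
    return tables


def load_reference_deltas() -> pd.DataFrame:
    """Load the packaged blank-subtracted calibration responses (two decimals)."""
    return _read_fixture("table2.csv")
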