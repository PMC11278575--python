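import pytest

from glucoloop.calibration import fit_calibration_curve
from glucoloop.fixtures import load_fixture_tables, load_reference_deltas


@pytest.fixture(scope="session")
def tables():
    """Packaged per-sensor calibration tables (sensors 1-5)."""
    return load_fixture_tables()


@pytest.fixture(scope="session")
def reference_deltas():
    """Packaged blank-subtracted responses printed at two decimals."""
    return load_reference_deltas()


@pytest.fixture(scope="session")
def curves(tables):
    """Deterministic 4PL fits of all packaged sensors."""
    return {sid: fit_calibration_curve(tbl) for sid, tbl in tables.items()}
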