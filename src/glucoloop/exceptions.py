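"""Exception hierarchy shared across the package."""


class GlucoLoopError(Exception):
    """Base class for all package-specific errors."""


class InvalidTraceError(GlucoLoopError, ValueError):
    """A chronoamperometric trace violates its structural contract."""


class DataError(GlucoLoopError, ValueError):
    """Input data are malformed (non-finite, duplicated, unsorted...)."""


class ConfigurationError(GlucoLoopError, ValueError):
    """A configuration object or generator spec is invalid."""


class FitError(GlucoLoopError, RuntimeError):
    """Calibration-curve fitting failed or is infeasible."""


class StateError(GlucoLoopError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class SafetyError(GlucoLoopError, RuntimeError):
    """A simulated electrical/thermal safety limit would be exceeded."""


class IntegrityError(GlucoLoopError, RuntimeError):
    """Packaged fixture data failed its checksum verification."""


class InsufficientDataError(DataError):
    """Too few replicates/points for the requested statistic."""
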