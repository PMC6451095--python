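"""Exception hierarchy shared across the package."""


class SmfociError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(SmfociError, ValueError):
    """Invalid cell geometry (e.g. length shorter than width)."""


class ConfigError(SmfociError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class ConsistencyError(SmfociError, ValueError):
    """Inputs that disagree with each other (unknown cell ids, foci
    outside every outline, mixed time points, mismatched grids)."""


class CalibrationError(SmfociError, RuntimeError):
    """Single-molecule intensity calibration could not be performed."""


class FitError(SmfociError, RuntimeError):
    """A model fit failed to converge; carries diagnostics in args."""
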