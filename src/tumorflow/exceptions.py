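"""Exception hierarchy."""


class TumorflowError(Exception):
    """Base class for package errors."""


class NetworkParseError(TumorflowError):
    """A network file could not be parsed; message names the offending record."""


class NetworkValidationError(TumorflowError):
    """A network violates a structural invariant."""


class SolverError(TumorflowError):
    """A linear or fixed-point solve failed."""


class ConfigurationError(TumorflowError):
    """Invalid or inconsistent configuration."""


class CalibrationError(TumorflowError):
    """Boundary-condition calibration exhausted its search space."""
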