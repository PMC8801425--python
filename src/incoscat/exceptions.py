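"""Exception hierarchy for incoscat."""


class IncoscatError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(IncoscatError, ValueError):
    """A model parameter is outside its physical domain."""


class GridError(IncoscatError, ValueError):
    """An energy/momentum grid violates a contract (e.g. non-uniform omega)."""


class FormatError(IncoscatError, ValueError):
    """A data file does not conform to the columnar format.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class NormalizationError(IncoscatError, ValueError):
    """Reference-curve normalization is impossible (zero reference intensity)."""


class FitError(IncoscatError, RuntimeError):
    """An optimizer failed to converge; carries diagnostics where possible."""


class FitWindowError(FitError):
    """No admissible Q-window with enough points for the elastic-scan fit."""


class ConfigError(IncoscatError, ValueError):
    """Pipeline configuration failed validation before execution."""
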