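"""Exception hierarchy shared across the package.

Distinct classes exist so that the command-line layer can map failures to
distinct exit codes (configuration vs. parsing vs. numerics).
"""


class DeltaPointError(Exception):
    """Base class for all package errors."""


class ParameterError(DeltaPointError, ValueError):
    """A parameter is outside its mathematical domain (e.g. non-positive variance)."""


class ConfigError(DeltaPointError, ValueError):
    """A run configuration is inconsistent (e.g. training prefix too short)."""


class ParseError(DeltaPointError, ValueError):
    """An input file could not be parsed into a valid time series."""


class NumericalError(DeltaPointError, RuntimeError):
    """A linear-algebra or optimisation step failed numerically."""


class FittingError(NumericalError):
    """Hyperparameter optimisation failed in every restart.

    Carries the best objective value seen so far in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EvaluationError(DeltaPointError, ValueError):
    """A detection-evaluation request is ill-posed (e.g. no detections)."""
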