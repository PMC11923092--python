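"""Exception hierarchy.

Input/configuration problems and fit failures are distinct so callers (and
the CLI exit codes) can tell a bad file from a model that would not converge.
"""


class InteinKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InteinKitError):
    """Invalid configuration or input data (missing mass, bad schema, ...)."""


class DomainError(InteinKitError):
    """Argument outside the mathematical domain of an operation."""


class FitError(InteinKitError):
    """Nonlinear fit failed to converge or is unidentifiable.

    Carries optional diagnostics (start points tried, per-regression tables).
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ModelInconsistencyError(FitError):
    """Extracted parameters violate the model (negative rate, zero slope)."""
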