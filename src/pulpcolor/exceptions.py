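"""Exception and warning hierarchy shared across the package."""


class PulpcolorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PulpcolorError, ValueError):
    """Invalid user input, configuration or table row."""


class SchemaError(ValidationError):
    """Input table is missing required columns or is empty."""


class DomainError(PulpcolorError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class SingularSystemError(PulpcolorError):
    """Normal equations are rank-deficient; no unique least-squares solution."""


class InsufficientDataError(PulpcolorError):
    """Too few rows for the requested fit (a 4-parameter model needs >= 5)."""


class UndefinedCorrelationError(PulpcolorError):
    """Pearson correlation undefined because a column is constant."""


class AssayWarning(UserWarning):
    """Non-fatal assay condition, e.g. signal below the detection limit."""


class NegativePredictionWarning(UserWarning):
    """A linear color model extrapolated to a negative content value."""
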