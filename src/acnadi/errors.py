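"""Exception hierarchy shared across the package."""


class AcnAdiError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AcnAdiError):
    """Invalid generator or pipeline configuration."""


class SchemaError(AcnAdiError):
    """Input table is missing required columns or contains unknown terms."""


class ValidationError(AcnAdiError):
    """Input rows violate eligibility or referential-integrity rules."""


class DegenerateInputError(AcnAdiError):
    """Input is structurally valid but statistically degenerate
    (single-class outcome, zero-variance column, empty group, ...)."""


class CollinearityError(AcnAdiError):
    """Design matrix is rank deficient; the message names an aliased term."""


class CalibrationError(AcnAdiError):
    """Intercept calibration target is unattainable."""


class ConvergenceError(AcnAdiError):
    """An iterative fit failed to converge within its iteration budget."""


class StratificationError(AcnAdiError):
    """Cross-validation folds cannot be stratified (a fold has one class)."""
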