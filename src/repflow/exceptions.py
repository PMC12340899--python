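"""Exception hierarchy shared across the package."""


class RepflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RepflowError):
    """Invalid configuration values (probabilities out of range, bad fractions...)."""


class InputError(RepflowError):
    """Malformed data passed to an operation (non-finite values, dimension mismatch)."""


class TrainingError(RepflowError):
    """Training contract violated (single-arm cohort, stage ordering...)."""


class DivergenceError(RepflowError):
    """Optimisation produced non-finite losses; carries diagnostics in args."""


class SeparationError(RepflowError):
    """Perfect separation detected in a logistic regression fit."""
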