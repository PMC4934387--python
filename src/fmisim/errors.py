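"""Exception hierarchy shared across the package."""


class FmisimError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FmisimError, ValueError):
    """An argument violates an operation's preconditions."""


class DegenerateVarianceError(FmisimError, ValueError):
    """A variance ratio is undefined (e.g. zero within-imputation variance)."""


class NoDonorError(FmisimError, ValueError):
    """Hot-deck imputation was asked to run with an empty donor set."""


class PoolExhaustedError(FmisimError, ValueError):
    """More imputations were requested than the pool holds."""


class SchemaError(FmisimError, KeyError):
    """A named column is absent from the table."""


class CalibrationError(FmisimError, RuntimeError):
    """Moment calibration failed; carries the achieved moments for diagnosis."""

    def __init__(self, message: str, achieved: dict | None = None):
        super().__init__(message)
        self.achieved = achieved or {}


class GroupingError(FmisimError, ValueError):
    """A grouping request is incompatible with the data (too few distinct values)."""


class EmptyPatternError(FmisimError, ValueError):
    """A requested missingness level rounds to zero missing rows."""


class UnbalancedDesignError(FmisimError, ValueError):
    """The factorial ANOVA requires equal replicates in every cell."""


class ConfigError(FmisimError, ValueError):
    """A run configuration is internally inconsistent."""


class ValidationError(FmisimError, ValueError):
    """An input file does not match the expected schema."""
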