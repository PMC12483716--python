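"""Exception hierarchy shared across the package."""


class EirmixError(Exception):
    """Base class for all package errors."""


class SchemaError(EirmixError):
    """A required column is missing or the predictor schema is malformed."""


class DataValidationError(EirmixError):
    """Input rows violate the long-format contract (duplicates, bad response codes)."""


class ConsistencyError(DataValidationError):
    """A person- or item-level predictor varies within its cluster."""


class EncodingError(EirmixError):
    """A category unseen in the schema appeared at transform time."""


class EmptyFeatureError(EirmixError):
    """Preprocessing dropped every predictor."""


class DesignError(EirmixError):
    """Design matrix is rank deficient or dimensions do not line up."""


class ConvergenceError(EirmixError):
    """An iterative fit failed to converge (e.g. separation)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ParameterError(EirmixError):
    """An invalid tuning or control parameter was supplied."""


class GenerationError(EirmixError):
    """The synthetic-data generator could not satisfy its constraints."""


class UndefinedResultError(EirmixError):
    """A statistic is undefined for the given input (e.g. constant predictions)."""
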