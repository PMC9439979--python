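"""Exception hierarchy shared across the package."""


class CovprojError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CovprojError):
    """A role/group configuration names a column or group that does not exist."""


class CompleteCaseError(CovprojError):
    """Input table contains missing cells; the method requires complete cases."""

    def __init__(self, message: str, samples=None):
        super().__init__(message)
        self.samples = list(samples) if samples is not None else []


class DomainError(CovprojError):
    """A value is outside the mathematical domain of an operation (e.g. log of <= 0)."""


class DegenerateError(CovprojError):
    """Zero-variance or otherwise degenerate input vector/matrix."""


class RankError(CovprojError):
    """Requested number of components exceeds the rank of the data."""


class UsageError(CovprojError):
    """Operation applied in an invalid state (e.g. projecting an already-zeroed column)."""
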