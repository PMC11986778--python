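"""Exception hierarchy shared across the package."""


class NeighSDQError(Exception):
    """Base class for all package errors."""


class SchemaError(NeighSDQError):
    """A table is missing mandatory columns or has the wrong layout."""


class IntegrityError(NeighSDQError):
    """A table violates a data invariant (duplicates, out-of-range values)."""


class DomainError(NeighSDQError, ValueError):
    """A scalar argument is outside its documented domain."""


class SpecError(NeighSDQError):
    """A model specification refers to unknown terms or is inconsistent."""


class DataError(NeighSDQError):
    """A dataset is unusable for the requested operation (e.g. zero rows)."""


class ConfigError(NeighSDQError):
    """A configuration object holds impossible values."""


class ConvergenceError(NeighSDQError):
    """MCMC diagnostics exceeded their thresholds in strict mode."""
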