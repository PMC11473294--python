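"""Exception hierarchy shared across the pipeline stages."""


class IneqdecompError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IneqdecompError):
    """A configuration value is invalid or inconsistent (CLI exit code 2)."""


class DataError(IneqdecompError):
    """Input records violate a stage precondition (CLI exit code 3)."""


class DegenerateTableError(DataError):
    """A contingency table cannot support a chi-squared test."""


class UndefinedIndexError(DataError):
    """A concentration index is undefined (zero-prevalence outcome)."""


class ModelFitError(IneqdecompError):
    """Maximum-likelihood estimation failed (CLI exit code 4)."""
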