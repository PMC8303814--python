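"""Exception hierarchy and data-quality warning category shared across the package."""


class NormdoseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NormdoseError):
    """An input value violates a documented precondition (negative dose factor,
    inverted usage times, out-of-range occupancy, ...)."""


class CompletenessError(NormdoseError):
    """A required (nuclide, age group, pathway) cell or a whole nuclide is missing
    from a table that must be complete."""


class NotAvailableError(NormdoseError):
    """A lookup addressed a combination the coefficient tables legitimately do not
    carry (e.g. K-40 inhalation for absorption types other than F)."""


class UsageError(NormdoseError):
    """An API was called with arguments that contradict each other (e.g. an
    absorption type supplied for a non-inhalation pathway, unknown unit token)."""


class ConfigurationError(NormdoseError):
    """A run configuration is incomplete or inconsistent (e.g. absorption policy
    missing a nuclide that has several absorption types)."""


class FormatError(NormdoseError):
    """A delimited input file or a duration string could not be parsed."""


class DataQualityWarning(UserWarning):
    """Raised (once per load) for known anomalies carried verbatim in the packaged
    reference tables, so downstream users can audit them."""
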