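"""Exception hierarchy shared across the package."""


class EsourceError(Exception):
    """Base class for all package errors."""


class SchemaError(EsourceError):
    """A field dictionary or serialized document violates its schema."""


class InvariantError(EsourceError):
    """A domain-type invariant is violated (e.g. transferable but not EHR-available)."""


class ConfigError(EsourceError, ValueError):
    """A study, deidentification or pipeline configuration is inconsistent.

    Also a ValueError so that pydantic model validators surface it as a
    standard validation failure.
    """


class PolicyError(EsourceError):
    """An operation was attempted out of policy order (e.g. extraction before deidentification)."""


class PushStateError(EsourceError):
    """One-time push semantics violated (second push without force)."""


class IntegrityError(EsourceError):
    """Checksum or manifest verification failed."""


class DomainError(EsourceError):
    """A value falls outside the configured domain (e.g. age outside all bins)."""


class MetricUndefinedError(EsourceError):
    """A quality metric was requested on an empty denominator."""


class ReportError(EsourceError):
    """A quality report cannot be assembled (missing modules)."""
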