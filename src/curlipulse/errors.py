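"""Exception hierarchy shared across the package."""


class CurlipulseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CurlipulseError, ValueError):
    """A simulation or analysis parameter is invalid; the message names the field."""


class InvalidTraceError(CurlipulseError, ValueError):
    """A lineage trace violates a structural requirement (empty, non-positive lengths...)."""


class InsufficientDataError(CurlipulseError, ValueError):
    """Too few observations for the requested estimator."""


class EmptyProfileError(CurlipulseError, ValueError):
    """No trace crosses the threshold, so no aligned profile exists."""


class SchemaError(CurlipulseError, ValueError):
    """An input table is missing a required column; the message names it."""


class FormatError(CurlipulseError, ValueError):
    """An input table is structurally malformed (e.g. non-uniform frame spacing)."""


class InvalidArgumentsError(CurlipulseError, ValueError):
    """Mutually inconsistent arguments (e.g. baseline above peak)."""
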