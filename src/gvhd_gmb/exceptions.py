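"""Exception hierarchy shared across the package.

Everything derives from :class:`GvhdGmbError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
failure modes of the individual stages (file format, value domain,
configuration, model fitting/scoring, pipeline orchestration).
"""


class GvhdGmbError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GvhdGmbError, ValueError):
    """A file or token does not conform to the expected text format."""


class DomainError(GvhdGmbError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class ConfigurationError(GvhdGmbError, ValueError):
    """A configuration field is invalid; the message names the field."""


class FittingError(GvhdGmbError, ValueError):
    """Model fitting is impossible on the provided training data."""


class ScoringError(GvhdGmbError, ValueError):
    """A sample cannot be scored under the provided model."""


class PipelineError(GvhdGmbError, RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""
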