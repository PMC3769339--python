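"""Exception hierarchy for nmweber.

All errors raised by the library derive from :class:`NmweberError` so callers
can catch a single base class; the more specific subclasses separate domain
(argument) errors from data-format, pooling and fitting failures.
"""


class NmweberError(Exception):
    """Base class for all nmweber errors."""


class DomainError(NmweberError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FormatError(NmweberError, ValueError):
    """A file or record does not conform to the expected schema."""


class EmptyDataError(NmweberError, ValueError):
    """An operation received no usable observations."""


class ClassificationError(NmweberError, ValueError):
    """A performance record cannot be assigned to the HIGH or LOW set."""


class PoolingError(NmweberError, ValueError):
    """Records cannot be pooled because their condition keys disagree."""


class FitError(NmweberError, RuntimeError):
    """Parameter estimation failed on a degenerate or unusable design."""


class ComparisonError(NmweberError, ValueError):
    """Two fits are not a valid nested pair for model comparison."""
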