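"""Exception hierarchy.

All errors raised by this package derive from :class:`PeachSpecError` so
callers can catch one base class; parameter problems additionally derive
from ``ValueError`` to behave idiomatically.
"""


class PeachSpecError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PeachSpecError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateSampleError(PeachSpecError, ValueError):
    """A fruit has too few scans for a valid three-zone split."""


class DegenerateSpectrumError(PeachSpecError, ValueError):
    """A spectrum has zero variance and cannot be SNV-normalised."""


class UndefinedCorrelationError(PeachSpecError, ValueError):
    """Pearson correlation is undefined (a constant vector)."""


class IntegrityError(PeachSpecError):
    """Scan table and metadata table disagree about sample identity."""


class FormatError(PeachSpecError):
    """An on-disk file does not parse as the expected format."""


class UnsupportedFormatError(FormatError):
    """A serialized object carries an unknown version tag."""
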