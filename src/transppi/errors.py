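"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`TransppiError`, so callers can catch one type at pipeline level.
"""


class TransppiError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TransppiError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(TransppiError, ValueError):
    """Too few observations to define the requested statistic."""


class UndefinedTestError(TransppiError, ValueError):
    """The test statistic is undefined (for example zero dosage variance)."""


class FeasibilityError(TransppiError, ValueError):
    """A sampling or planting request cannot be satisfied by the inputs."""


class ConsistencyError(TransppiError, ValueError):
    """Cross-referenced inputs disagree (unknown gene, misaligned samples...)."""


class NoPathError(TransppiError, ValueError):
    """Two nodes lie in different connected components."""


class FormatError(TransppiError, ValueError):
    """A file does not conform to the expected text format."""
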