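"""Exception hierarchy shared by all pipeline stages.

Validation problems (bad inputs, malformed tables) raise
:class:`ValidationError`; analysis-stage failures on structurally valid
input raise more specific subclasses so callers can map them onto exit
codes or per-record flags.
"""


class ComboscreenError(Exception):
    """Base class for every error raised by this package."""


class ValidationError(ComboscreenError, ValueError):
    """Input failed validation (range, schema, or invariant violation)."""


class EmptyInputError(ValidationError):
    """An operation received an empty collection where data is required."""


class UnscorableError(ComboscreenError):
    """A score is mathematically undefined for the given inputs."""


class MissingConditionError(ComboscreenError):
    """A required experimental condition is absent from the input."""


class DegenerateDesignError(ComboscreenError):
    """The design matrix for a fit is rank-deficient (e.g. a single dose)."""


class NonMonotoneResponseError(ComboscreenError):
    """A dose-response fit produced a non-positive slope."""


class NoOverlapError(ComboscreenError):
    """A gene set shares no members with the rank it is scored against."""
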