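"""Exception hierarchy for kronpair.

All library errors derive from :class:`KronpairError` so callers can catch
one base class at tool boundaries.
"""


class KronpairError(Exception):
    """Base class for all kronpair errors."""


class IdentifierError(KronpairError):
    """Duplicate, unknown, or mismatched drug/target identifiers."""


class FormatError(KronpairError):
    """Malformed input file (ragged rows, bad header, unparseable cell)."""


class ShapeError(KronpairError):
    """Array or matrix dimensions inconsistent with the operation."""


class DomainError(KronpairError):
    """A value lies outside the mathematical domain of a transform."""


class StateError(KronpairError):
    """Operation applied to a table in the wrong label state."""


class EmptyDataError(KronpairError):
    """No measured entries where at least one is required."""


class NormalizationError(KronpairError):
    """Similarity matrix cannot be cosine-normalized (nonpositive diagonal)."""


class ConditioningError(KronpairError):
    """A solver denominator is numerically too close to zero."""


class FoldError(KronpairError):
    """Requested cross-validation folds are infeasible for the data."""


class EvaluationError(KronpairError):
    """Evaluation produced no defined metric value at all."""
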