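"""Exception hierarchy.

Every error raised by this package derives from :class:`DocRefineError`, so
callers can catch one type at a pipeline boundary while tests can assert the
specific failure mode.
"""


class DocRefineError(Exception):
    """Base class for all errors raised by docrefine."""


class SchemaError(DocRefineError):
    """A required column is missing or a table violates its schema."""


class ParseError(DocRefineError):
    """A cell or row of an input file could not be parsed; the message
    carries the 1-based (row, column) location where known."""


class InsufficientDataError(DocRefineError):
    """An input is too small for the requested operation (e.g. fewer than
    3 time points, fewer than 2 regions)."""


class SeedSelectionError(DocRefineError):
    """The CRS-R seed-selection rule produced an empty set, so the
    refinement cannot start."""


class DegenerateSignalError(DocRefineError):
    """A region's time series has zero temporal variance, making Pearson
    correlation undefined."""


class DomainError(DocRefineError):
    """A value lies outside the mathematical domain of an operation
    (e.g. |r| >= 1 passed to the Fisher transform)."""


class IntegrityError(DocRefineError):
    """An internal consistency check failed (e.g. a connectivity matrix
    asymmetric beyond tolerance)."""


class InsufficientGroupError(DocRefineError):
    """A group has too few subjects for the requested statistic."""


class ShapeError(DocRefineError):
    """Edge vectors or matrices with mismatched dimensions were combined."""


class EmptyEdgeSetError(DocRefineError):
    """A contrast produced an empty decreased or increased edge set, so
    DCI/ICI are undefined; the message names the empty set."""


class DegenerateGroupError(DocRefineError):
    """A group model cannot be fit (fewer than 3 members, or a covariance
    that stays singular after regularization)."""


class CollapseError(DocRefineError):
    """The refinement's selected set shrank below the minimum size needed
    to fit a group model; carries the trace up to failure in ``trace``."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class SplitError(DocRefineError):
    """A train/test split is infeasible (group too small, or a degenerate
    training set with one class absent)."""


class BlueprintError(DocRefineError):
    """A synthetic-cohort blueprint is invalid or numerically infeasible
    (e.g. deltas too large for a positive-definite correlation matrix)."""
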