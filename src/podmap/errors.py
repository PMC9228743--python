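"""Exception hierarchy for podmap.

Every validation failure raises a subclass of :class:`PodmapError` so callers
can distinguish bad inputs from programming errors.
"""


class PodmapError(Exception):
    """Base class for all podmap errors."""


class InvalidDesignError(PodmapError, ValueError):
    """Exposure design violates its invariants (ordering, positivity, counts)."""


class InvalidSpecError(PodmapError, ValueError):
    """A gene-surface or cell-trend specification violates its invariants."""


class DuplicateIdentifierError(PodmapError, ValueError):
    """Duplicate gene, sample, or animal identifiers."""


class MissingControlError(PodmapError, ValueError):
    """A treated sample/animal has no time-matched control."""


class InsufficientReplicationError(PodmapError, ValueError):
    """A condition has too few replicates for a two-sample test."""


class DegenerateDesignError(PodmapError, ValueError):
    """Model matrix is rank deficient (e.g. a single dose level)."""


class OutOfRangeError(PodmapError, ValueError):
    """Dose or time outside the design range for coordinate normalization."""


class InvalidPValueError(PodmapError, ValueError):
    """p-value outside its admissible range."""


class EmptyInputError(PodmapError, ValueError):
    """An operation that needs at least one element received none."""


class NotResponsiveError(PodmapError, ValueError):
    """A dPOD label was requested for a non-responsive activation map."""


class ShapeError(PodmapError, ValueError):
    """Grid/mask shape mismatch."""


class IncompleteProfileError(PodmapError, ValueError):
    """A gene lacks a dPOD label for one or more conditions."""


class SubsetError(PodmapError, ValueError):
    """Query gene set is not contained in the universe."""


class SchemaError(PodmapError, ValueError):
    """An input file does not conform to the declared schema."""
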