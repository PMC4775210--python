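"""Exception hierarchy.

All package errors derive from :class:`EatmapError` so callers can catch
broadly; the subclasses distinguish the failure modes the pipeline surfaces
(invalid objects, unreadable files, empty decay selections, unsatisfiable
analysis windows, failed fits).
"""


class EatmapError(Exception):
    """Base class for all errors raised by eatmap."""


class InvariantError(EatmapError, ValueError):
    """A domain object violates one of its declared invariants."""


class SchemaError(EatmapError):
    """A recording file has a recognizable container but the wrong schema
    (missing fields, mismatched decay bin count, unknown schema version)."""


class CorruptFileError(EatmapError):
    """A recording file cannot be parsed as an HDF5 container at all."""


class EmptySelectionError(EatmapError):
    """A cycle selector matched no cycles: no decays to pool."""


class WindowUnsatisfiedError(EatmapError):
    """The pooled inter-RBC window cannot be filled, e.g. because RBC flow
    is too fast for any mid-distance decays to exist."""


class FitError(EatmapError):
    """A lifetime fit failed outright (degenerate input) or a downstream
    quantity depends on a fit that did not converge."""
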