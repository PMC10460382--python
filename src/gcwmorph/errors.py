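"""Exception hierarchy for gcwmorph.

All package errors derive from :class:`GCWMorphError` so callers can catch
one base class at pipeline boundaries.
"""


class GCWMorphError(Exception):
    """Base class for all gcwmorph errors."""


class ValidationError(GCWMorphError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(GCWMorphError, ValueError):
    """A file on disk is missing, corrupted, or contradicts its metadata."""


class ParameterError(GCWMorphError, ValueError):
    """A parameter value is outside its admissible range."""


class InputError(GCWMorphError, ValueError):
    """An operation received an input it cannot process (e.g. empty mask)."""


class PlacementError(GCWMorphError, RuntimeError):
    """Granule placement could not reach the requested packing after bounded retries."""
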