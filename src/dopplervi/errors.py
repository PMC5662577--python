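"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`DoppleviError`, so callers can catch the whole family at a batch
boundary (the CLI does exactly that) while still distinguishing the
specific failure modes that matter for annotated-image input.
"""


class DoppleviError(Exception):
    """Base class for all errors raised by dopplervi."""


class ValidationError(DoppleviError, ValueError):
    """An argument or data structure violates a documented precondition."""


class InputFormatError(DoppleviError):
    """A file decoded, but not as a supported lossless 8-bit raster."""


class MissingOutlineError(DoppleviError):
    """No pixel of the annotation color was found in the image."""


class OpenContourError(DoppleviError):
    """The annotation outline does not enclose any interior.

    Flood fill from the image border reached every non-outline pixel,
    i.e. the hand-drawn contour has a gap.
    """


class AmbiguousOutlineError(DoppleviError):
    """Multiple disjoint closed outlines were found and no selection policy set."""


class EmptyRegionError(DoppleviError):
    """A vascular index was requested for a region with zero pixels."""


class SchemaError(DoppleviError):
    """A cohort table is missing required columns or has malformed values."""
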