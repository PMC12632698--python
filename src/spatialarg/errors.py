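"""Exception hierarchy.

Errors are split by how a caller (and the CLI exit-code mapping) should
treat them: malformed input files, invariant violations of an otherwise
well-formed object, and numerical failures during inference.
"""


class SpatialARGError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SpatialARGError):
    """A file could not be parsed (malformed tables, bad CSV schema)."""


class ValidationError(SpatialARGError):
    """An object violates a structural invariant (e.g. parent not older
    than child, sample without a location, degenerate window)."""


class StructuralError(ValidationError):
    """The genomic structure is inconsistent (edge coverage gap, node
    with no parent that is not a root)."""


class NumericalError(SpatialARGError):
    """A numerical routine failed (singular system, zero-length branch)."""
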