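"""Exception types raised by hippomorph measurements.

Measurement functions distinguish *absence* (a legal outcome, returned as
``None``) from *errors* (contract violations that make a slice or case
unusable). Only the latter raise.
"""


class HippomorphError(Exception):
    """Base class for all hippomorph errors."""


class SchemaError(HippomorphError):
    """Label codes in a volume do not match the subfield schema."""


class FormatError(HippomorphError):
    """Input file is not an integer-valued label map."""


class OrientationError(HippomorphError):
    """NIfTI orientation metadata is ambiguous or degenerate."""


class LandmarkError(HippomorphError):
    """A required landmark is missing or ill-ordered."""


class TopologyError(HippomorphError):
    """A mask does not have the topology a measurement requires."""


class ProjectionError(HippomorphError):
    """SRLM projection is impossible on this slice (e.g. no CA voxels)."""


class AnchorError(HippomorphError):
    """The medial-anchor march never reached SUB or CA1."""


class PhantomSpecError(HippomorphError):
    """A phantom specification violates its own invariants."""


class DegenerateSliceError(HippomorphError):
    """A slice is too degenerate to measure (zero-length path etc.)."""
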