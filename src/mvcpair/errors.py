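"""Exception hierarchy for the pair-matching pipeline."""


class MvcError(Exception):
    """Base class for all package errors."""


class MeshFormatError(MvcError):
    """A mesh file could not be parsed, or violates basic invariants
    (non-finite coordinates, out-of-range face indices)."""


class EmptyMeshError(MeshFormatError):
    """A mesh has no faces after reading and cleaning."""


class DuplicateIdError(MvcError):
    """Two specimens in one collection map to the same identifier."""


class DegenerateGeometryError(MvcError):
    """A rigid-motion estimate is underdetermined (collinear points,
    parallel normals, ...). The message names the unconstrained motion
    when it can be identified."""


class AlignmentFailureError(MvcError):
    """Fine alignment rejected every correspondence; the registration
    result would be meaningless and is reported as failed instead."""
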