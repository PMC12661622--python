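"""Exception hierarchy for the DTI-ALPS pipeline."""


class DtiAlpsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DtiAlpsError):
    """A file's structure does not match its declared format."""


class ValidationError(DtiAlpsError):
    """A value violates a domain invariant."""


class SchemaError(DtiAlpsError):
    """A table is missing required columns."""


class GeometryError(DtiAlpsError):
    """An ROI does not fit on, or lies outside, the target grid."""


class ExtractionError(DtiAlpsError):
    """An ROI intersects no valid voxels."""


class ComputationError(DtiAlpsError):
    """A quantity is undefined for the given inputs (e.g. non-positive denominator)."""


class ModelError(DtiAlpsError):
    """A statistical model cannot be estimated on the given design."""
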