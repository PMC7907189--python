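"""Exception hierarchy for the lesionmap package."""


class LesionMapError(Exception):
    """Base class for all package errors."""


class FormatError(LesionMapError):
    """A file could not be parsed as the expected format."""


class AlignmentError(LesionMapError):
    """Two volume grids do not share shape, spacing, or affine."""


class EmptyMaskError(LesionMapError):
    """A lesion mask entering analysis has no nonzero voxel."""


class ValidationError(LesionMapError):
    """A record or type invariant is violated."""


class SchemaError(LesionMapError):
    """A tabular input is missing required columns."""


class LandmarkError(LesionMapError):
    """Subfield landmarks are inconsistent with the grid."""


class ConfigError(LesionMapError):
    """A simulation or pipeline configuration is invalid."""


class DesignError(LesionMapError):
    """A regression design matrix is degenerate (collinear or single-class)."""


class CoverageError(LesionMapError):
    """A seed region falls outside the field of view of a volume."""


class DataError(LesionMapError):
    """An input dataset is empty or unusable."""


class StageError(LesionMapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
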