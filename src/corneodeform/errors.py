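"""Structured exceptions raised by the analysis pipeline.

Every error names the stage (and, where it applies, the frame) that failed,
so that batch drivers can report which part of a sequence was unusable.
"""


class CorneoDeformError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedFormatError(CorneoDeformError):
    """Input container format is not supported (e.g. the proprietary .cst)."""


class DimensionError(CorneoDeformError):
    """Frames of a sequence do not share a single height/width."""


class TooShortSequenceError(CorneoDeformError):
    """A sequence has fewer than two frames; decomposition needs a reference
    frame plus at least one more."""


class ConfigurationError(CorneoDeformError):
    """A configuration value violates its documented bound."""


class ContourNotFoundError(CorneoDeformError):
    """A frame has too few edge columns to trace the corneal contour."""

    def __init__(self, frame_index: int, n_edge_columns: int, n_columns: int):
        self.frame_index = frame_index
        super().__init__(
            f"contour not found in frame {frame_index}: only "
            f"{n_edge_columns}/{n_columns} columns contain an edge pixel "
            f"(need at least 10%); the corneal band may not be fully visible"
        )


class DegenerateRangeError(CorneoDeformError):
    """The deformation support range of a frame is too narrow to define the
    symmetry axis (fewer than 3 columns, or coincident endpoints)."""


class InsufficientDeformationError(CorneoDeformError):
    """The deformation-length-to-amplitude ratio is defined on too few frames
    for applanation peaks to be located."""
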