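"""Exception hierarchy for the strain pipeline.

Every error carries enough context (frame index, offending path) for a
batch run over a clinical video to report *where* a frame failed, since a
single bad segmentation mask should not silently corrupt a strain curve.
"""


class DTWStrainError(Exception):
    """Base class for all pipeline errors."""


class EmptyInput(DTWStrainError):
    """No frames found at the input location."""


class ShapeMismatch(DTWStrainError):
    """Frames in a sequence do not share a common shape."""


class NoForeground(DTWStrainError):
    """A mask frame contains no foreground pixels."""


class KeypointFailure(DTWStrainError):
    """Septal/lateral annulus or apex detection failed on a frame."""


class SplitFailure(DTWStrainError):
    """Cutting the closed boundary at the base caps did not yield two arcs."""


class DegenerateArc(DTWStrainError):
    """A contour arc has zero length and cannot be resampled."""


class PartitionFailure(DTWStrainError):
    """Too few DTW path nodes to place the requested block borders."""


class FrameMismatch(DTWStrainError):
    """Tracking-point table and mask sequence disagree on frame count."""


class SelfIntersection(DTWStrainError):
    """Phantom band self-intersects (thickness exceeds curvature radius)."""


class InvalidReference(DTWStrainError):
    """End-diastolic reference length is non-positive."""
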