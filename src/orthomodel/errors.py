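"""Exception hierarchy.

Every stage raises a subclass of :class:`OrthoModelError` so pipeline
drivers can distinguish stage failures from programming errors.
"""


class OrthoModelError(Exception):
    """Base class for all package errors."""


class ParameterError(OrthoModelError, ValueError):
    """An argument violates a precondition (out of range, wrong sign...)."""


class InputError(OrthoModelError, ValueError):
    """User-supplied data is unusable (too few seeds, too few landmarks...)."""


class ShapeError(OrthoModelError, ValueError):
    """Array shapes are inconsistent (ragged image stacks...)."""


class PlacementError(OrthoModelError):
    """Phantom teeth overlap on the arch."""

    def __init__(self, id_a: str, id_b: str):
        self.pair = (id_a, id_b)
        super().__init__(f"tooth phantoms {id_a} and {id_b} interpenetrate")


class ConvergenceError(OrthoModelError):
    """Registration ran out of usable correspondences."""


class ReconstructionError(OrthoModelError):
    """Surface reconstruction impossible (degenerate or under-sampled cloud)."""


class SegmentationError(OrthoModelError):
    """Crown/gingiva partition failed for a tooth."""


class AlignmentError(OrthoModelError):
    """Crown-to-volume mating produced no usable pairs."""


class SweepError(OrthoModelError):
    """Threshold sweep produced no informative iso-surfaces."""


class ManualInitRequired(OrthoModelError):
    """Crown-guided initialization found no slice; the impacted-tooth path
    needs an operator-supplied contour."""


class PropagationError(OrthoModelError):
    """Slice-to-slice level-set propagation diverged."""

    def __init__(self, slice_index: int, message: str = ""):
        self.slice_index = slice_index
        super().__init__(message or f"propagation diverged at slice {slice_index}")


class FusionError(OrthoModelError):
    """Crown and root meshes do not overlap; misalignment suspected."""


class FrameError(OrthoModelError):
    """Bodies carry inconsistent frame metadata."""


class FormatError(OrthoModelError):
    """A file on disk violates its format contract (DICOM tags, units...)."""


class LookupError_(OrthoModelError, KeyError):
    """Unknown tooth id."""


class ConfigError(OrthoModelError, ValueError):
    """Pipeline configuration rejected (unknown keys, bad values)."""
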