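"""Named error types raised across the pipeline."""


class LVFlowError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(LVFlowError):
    """Velocity component volumes (or masks) disagree in shape or frame count."""


class MissingSidecarKeyError(LVFlowError):
    """Required metadata keys absent from a sidecar file."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"sidecar is missing required keys: {', '.join(self.missing)}")


class OutOfFieldError(LVFlowError):
    """A queried position lies outside the velocity field's world extent."""


class EmptyMaskError(LVFlowError):
    """A segmentation mask has no foreground voxels."""


class DisjointGridsError(LVFlowError):
    """Source and target grids share no world-space overlap."""


class UnknownFieldKindError(LVFlowError):
    """Unrecognized analytic benchmark field kind."""


class PhantomSpecError(LVFlowError):
    """Phantom specification invalid or unrealizable on the requested grid."""
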