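"""Exception hierarchy for the flow4d pipeline stages."""


class Flow4dError(Exception):
    """Base class for all flow4d errors."""


class GeometryError(Flow4dError):
    """Phantom geometry does not fit the stated field of view."""


class NavigationError(Flow4dError):
    """Self-navigation signal could not be extracted."""


class GatingError(Flow4dError):
    """Heartbeat detection / cardiac gating failed."""


class ReconError(Flow4dError):
    """Reconstruction failure (empty frame, mismatched inputs, ...)."""


class SegmentationError(Flow4dError):
    """Lumen segmentation failure (seed outside vessel, ...)."""


class CenterlineError(Flow4dError):
    """Centerline extraction failure (branching skeleton, ...)."""


class PwvError(Flow4dError):
    """PWV stage failure (too few planes, degenerate fit, ...)."""


class WssError(Flow4dError):
    """WSS stage failure (all vertices flagged, ...)."""


class PipelineError(Flow4dError):
    """Pipeline orchestration failure; message names the stage."""
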