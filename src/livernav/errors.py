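"""Exception hierarchy for the navigation pipeline.

Every stage raises a subclass of :class:`LiverNavError`, so callers (and the
CLI) can distinguish configuration problems from runtime stage failures.
"""


class LiverNavError(Exception):
    """Base class for all package errors."""


class FrameError(LiverNavError):
    """Coordinate-frame labels do not chain (e.g. composing MRI->CT with CBCT->EM)."""


class ConfigError(LiverNavError):
    """Invalid or infeasible configuration (e.g. tumor larger than the liver)."""


class DegenerateGeometryError(LiverNavError):
    """Point configuration does not constrain a unique rigid transform."""


class CardinalityError(LiverNavError):
    """Point lists that must correspond have different lengths."""


class EmptyMaskError(LiverNavError):
    """A binary mask required for registration contains no voxels."""


class GroupingError(LiverNavError):
    """Detected blobs cannot be grouped into the expected tracker layout."""


class FormatError(LiverNavError):
    """Malformed on-disk file (header, schema or ordering violation)."""


class StageError(LiverNavError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
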