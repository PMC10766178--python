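"""Exception hierarchy shared by all pipeline stages.

Every stage raises a subclass of :class:`LfpError` so callers can attach
stage identity when propagating (see :func:`lfpmatch.matching.compare_images`).
"""


class LfpError(Exception):
    """Base class for all pipeline errors."""


class InvalidImageError(LfpError):
    """Input is not a well-formed raster (wrong dimensionality, empty, too small)."""


class DegenerateImageError(LfpError):
    """Image content defeats the operation (constant image, empty foreground)."""


class ConfigurationError(LfpError):
    """A parameter is out of range or inconsistent with the input."""


class NoCoreError(LfpError):
    """Orientation field contains no singular point usable as the core anchor."""


class NoFeaturesError(LfpError):
    """No usable feature points remain after extraction/filtering."""


class DegenerateGeometryError(LfpError):
    """Feature geometry makes the similarity ratio undefined (points on the core)."""


class NoOverlapError(LfpError):
    """Correspondence search accepted zero sample/control pairs."""


class PreconditionError(LfpError):
    """An operation was called outside its contract (e.g. off-skeleton pixel)."""


class StageError(LfpError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
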