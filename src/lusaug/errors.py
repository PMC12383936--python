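"""Exception hierarchy shared across the package."""


class LusaugError(Exception):
    """Base class for package errors."""


class ShapeMismatchError(LusaugError, ValueError):
    """Pixel grid and mask (or other paired grids) disagree in shape."""


class EmptyMaskError(LusaugError, ValueError):
    """An operation requiring a non-empty FOV mask received an empty one."""


class FitError(LusaugError, ValueError):
    """A mask is inconsistent with both the linear and the fan FOV model."""


class ParameterError(LusaugError, ValueError):
    """An invalid parameter value or configuration key."""


class MissingGeometryError(LusaugError, ValueError):
    """A geometry-aware transform received an image without FOV geometry."""
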