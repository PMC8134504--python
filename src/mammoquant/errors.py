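"""Exception types shared across the package."""


class MammoQuantError(Exception):
    """Base class for all package errors."""


class ParameterError(MammoQuantError, ValueError):
    """A parameter is outside its valid range."""


class DegenerateImageError(MammoQuantError, ValueError):
    """An image has no usable contrast (e.g. constant pixels)."""


class NoForegroundError(MammoQuantError, ValueError):
    """Segmentation produced an empty foreground after cleanup."""


class GenerationError(MammoQuantError, ValueError):
    """A synthetic scene cannot be rendered with the given parameters."""
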