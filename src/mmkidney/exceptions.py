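"""Exception types shared across the package."""


class MMKidneyError(Exception):
    """Base class for package-specific errors."""


class InvalidAxisError(MMKidneyError, ValueError):
    """A wavenumber axis is missing, non-increasing, or out of range."""


class AxisMismatchError(MMKidneyError, ValueError):
    """Two spectral objects do not share a common wavenumber axis."""


class FormatError(MMKidneyError, ValueError):
    """A file's layout disagrees with its sidecar or metadata."""


class GeometryError(MMKidneyError, ValueError):
    """A phantom or measurement geometry is impossible (e.g. sphere larger than volume)."""
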