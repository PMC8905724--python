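"""Exception hierarchy shared across the package.

All errors derive from :class:`SonoquantError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
the handful of failure modes the pipeline can hit (incompatible grids,
empty measurement regions, impossible geometry, too-small samples, bad
parameters, unreadable files).
"""


class SonoquantError(Exception):
    """Base class for all package errors."""


class FormatError(SonoquantError):
    """A file could not be read as the expected format."""


class CongruenceError(SonoquantError):
    """Volumes that must share a grid (shape, spacing, affine) do not."""


class EmptyRegionError(SonoquantError):
    """A measurement region contains no voxels."""


class GeometryError(SonoquantError):
    """An implant-anchored region falls outside the grid or brain."""


class SampleSizeError(SonoquantError):
    """Too few observations for the requested statistic."""


class ParameterError(SonoquantError, ValueError):
    """An argument is outside its documented domain."""
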