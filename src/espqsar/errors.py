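"""Exception hierarchy for espqsar.

Every error raised on bad scientific input derives from :class:`EspQsarError`
so callers can distinguish domain failures from programming bugs.
"""


class EspQsarError(Exception):
    """Base class for all espqsar domain errors."""


class CubeFormatError(EspQsarError):
    """A cube file's header or records violate the format."""


class TruncationError(CubeFormatError):
    """A cube file's value section does not match the declared grid size."""


class SchemaError(EspQsarError):
    """A descriptor table is missing required columns or is empty."""


class TableParseError(EspQsarError):
    """A descriptor-table cell could not be parsed as a number."""


class SingularityError(EspQsarError):
    """A potential was requested at (or too close to) a nucleus."""


class EmptySurfaceError(EspQsarError):
    """Isosurface extraction found no density crossing, or a surface has no samples."""


class ExtrapolationError(EspQsarError):
    """Interpolation was requested outside the grid's bounding box."""


class CollinearityError(EspQsarError):
    """The regression design matrix is rank deficient."""


class DegreesOfFreedomError(EspQsarError):
    """Too few observations for the requested number of predictors."""


class BoundaryLeakError(EspQsarError):
    """A synthetic density grid has non-negligible density on its boundary."""
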