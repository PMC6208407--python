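"""Exception hierarchy.

Errors are split into configuration problems (bad settings, caught before any
pixel is touched) and data problems (inputs that do not satisfy the contract
of an operation).  The CLI maps these onto distinct exit codes.
"""


class SvzMapError(Exception):
    """Base class for all package errors."""


class ConfigError(SvzMapError):
    """Invalid study configuration."""


class DataError(SvzMapError):
    """Invalid or inconsistent input data."""


class MissingFileError(DataError, FileNotFoundError):
    """A required image or trace file does not exist."""


class ChannelCountMismatchError(DataError):
    """The TIFF channel count does not match the configured channel mapping."""


class TraceOutOfBoundsError(DataError):
    """A trace or reference coordinate lies outside the image."""


class ContourTooShortError(DataError):
    """Traced contour is shorter than a single probe width."""


class DegenerateTangentError(DataError):
    """Contour tangent has zero length at a probe anchor."""


class ProbeOutsideImageError(DataError):
    """A probe rectangle contains no pixels after clipping to the image."""


class HistogramMismatchError(DataError):
    """Two histograms do not share bin edges or are not normalized."""


class DuplicateMeasurementError(DataError):
    """Two measurements claim the same (section, wall, probe) slot."""


class UnknownProbeError(DataError):
    """A manual height override references a probe that was never measured."""


class ColumnCountMismatchError(DataError):
    """Wall matrices that must share a section axis do not."""


class SectionCountMismatchError(DataError):
    """Animal datasets to be averaged cover different numbers of sections."""
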