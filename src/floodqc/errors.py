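"""Exception hierarchy for flood-field QC analysis."""


class FloodQCError(Exception):
    """Base class for all floodqc errors."""


class FormatError(FloodQCError):
    """A file is not in the expected format (missing pixel data, ragged CSV...)."""


class MetadataError(FloodQCError):
    """Required image metadata is missing or invalid; names the attribute."""


class GeometryError(FloodQCError):
    """Pixel geometry violates an assumption (e.g. non-square spacing)."""


class PixelSizeError(FloodQCError):
    """Pixel size falls outside the NEMA window and cannot be rebinned into it."""


class EmptyFovError(FloodQCError):
    """The image has no nonzero region to analyze."""


class FovTooSmallError(FloodQCError):
    """The field of view is too small for the requested statistic."""


class DataError(FloodQCError):
    """In-mask data violates a precondition (e.g. non-positive pixel values)."""


class DegenerateDataError(FloodQCError):
    """A statistic is undefined because the data carry no variation."""


class CollinearityError(FloodQCError):
    """A regression design is degenerate (all pair means equal)."""


class ParameterError(FloodQCError):
    """A synthetic-phantom parameter produces a physically invalid field."""
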