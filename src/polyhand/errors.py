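"""Exception hierarchy shared by all polyhand modules."""


class PolyhandError(Exception):
    """Base class for all polyhand errors."""


class FormatError(PolyhandError):
    """A file does not conform to the expected dialect (missing column, bad token)."""


class DataError(PolyhandError):
    """Well-formed file or container holding invalid data (NaN, bad labels, bad time)."""


class ParameterError(PolyhandError):
    """An argument is outside its documented range."""


class LengthError(PolyhandError):
    """A series is too short for the requested operation."""


class CoverageError(PolyhandError):
    """A required (finger, level) combination has no trials."""


class DegenerateDataError(PolyhandError):
    """Input is degenerate for the requested computation (zero variance, singular
    covariance, coincident sensors, undefined conditional)."""


class InsufficientDataError(PolyhandError):
    """Too few observations for a statistic to be defined."""


class ConfigError(PolyhandError):
    """Pipeline configuration is invalid (unknown key, missing path, bad range)."""
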