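"""Exception hierarchy for the sEMG feature pipeline."""


class SemgError(Exception):
    """Base class for all package errors."""


class ParseError(SemgError):
    """A delimited signal file contains a non-numeric cell."""


class ShapeError(SemgError):
    """A signal matrix has inconsistent row lengths or a bad orientation."""


class LengthError(SemgError):
    """A signal is too short for the requested operation."""


class ConfigError(SemgError):
    """Inconsistent configuration values (e.g. non-integer window length)."""


class StatisticsError(SemgError):
    """A statistic is undefined for the given sample (m < 4, zero variance)."""
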