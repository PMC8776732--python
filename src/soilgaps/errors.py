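"""Exception hierarchy for soilgaps."""


class SoilGapsError(Exception):
    """Base class for all soilgaps errors."""


class ChronologyError(SoilGapsError):
    """Raised when time arguments are not in the required order."""


class DuplicateRecordError(SoilGapsError):
    """Raised when a (timestamp, sensor) pair appears more than once in an input."""


class RecordFormatError(SoilGapsError):
    """Raised when an input file does not conform to the declared schema."""


class EligibilityError(SoilGapsError):
    """Raised when a donor/target pair cannot support a linear fit
    (insufficient overlap or a degenerate predictor)."""


class ConfigurationError(SoilGapsError):
    """Raised for invalid configuration values."""
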