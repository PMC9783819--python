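"""Exception hierarchy.

All package-specific failures derive from :class:`ChronovocError` so callers
can catch one base class; each subclass also derives from the closest builtin
(ValueError / ArithmeticError / RuntimeError) for idiomatic handling.
"""


class ChronovocError(Exception):
    """Base class for all chronovoc errors."""


class ConfigurationError(ChronovocError, ValueError):
    """Invalid simulation / run configuration (bad enum, non-finite value...)."""


class FormatError(ChronovocError, ValueError):
    """Malformed input data (table schema, unsorted peak list, bad mzML...)."""


class UnsupportedModeError(FormatError):
    """Input is structurally valid but in an unsupported mode (e.g. profile spectra)."""


class EmptyInputError(ChronovocError, ValueError):
    """An operation received no data at all."""


class InsufficientDataError(ChronovocError, ValueError):
    """Too few points for the requested statistic."""


class InsufficientSpanError(InsufficientDataError):
    """Chronogram does not span enough time (circadian analysis needs >= 48 h)."""


class UndefinedStatisticError(ChronovocError, ArithmeticError):
    """Statistic undefined for this input (e.g. zero variance)."""


class UndefinedRatioError(ChronovocError, ArithmeticError):
    """A ratio's denominator is zero or negative where positivity is required."""


class DegenerateBackgroundError(ChronovocError, ValueError):
    """Background series has zero variance; detection threshold undefined."""


class IncompleteEvidenceError(ChronovocError, ValueError):
    """A required descriptor is missing/failed, classification cannot proceed."""


class StageError(ChronovocError, RuntimeError):
    """A pipeline stage failed; message names the stage and condition."""
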