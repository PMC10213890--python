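"""Exception hierarchy for swayintensity.

All package-specific failures derive from :class:`SwayIntensityError` so callers
can catch one base class at pipeline boundaries.
"""


class SwayIntensityError(Exception):
    """Base class for all swayintensity errors."""


class ConfigurationError(SwayIntensityError):
    """A parameter or configuration value is invalid (e.g. cutoff >= Nyquist)."""


class InsufficientDataError(SwayIntensityError):
    """Too few observations to perform the requested computation."""


class IdentifiabilityError(SwayIntensityError):
    """A random-effect term cannot be separated from other terms or the residual."""


class UndefinedStatisticError(SwayIntensityError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class DegenerateDataError(SwayIntensityError):
    """Input carries no usable contrast (e.g. a single factor level)."""


class EmptyJoinError(SwayIntensityError):
    """A pairing/join step produced zero rows."""


class InputValidationError(SwayIntensityError):
    """An input file or record violates the documented schema."""
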