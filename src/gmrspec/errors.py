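"""Exception hierarchy for gmrspec.

Every error raised on a violated contract derives from :class:`GmrSpecError`
so callers (and the CLI) can map failures to exit codes without matching on
builtin exception types.
"""


class GmrSpecError(Exception):
    """Base class for all gmrspec errors."""


class ValidationError(GmrSpecError, ValueError):
    """An input violated a documented invariant or precondition."""


class DispersionRangeError(ValidationError):
    """Wavelength outside the validity window of a dispersion model."""


class NoGuidedModeError(GmrSpecError):
    """The layer stack supports no guided TE mode at this wavelength."""


class ConvergenceError(GmrSpecError):
    """An iterative solver failed to converge (e.g. the Bragg fixed point)."""


class EmptyLayoutError(ValidationError):
    """No grating period resonates inside the requested wavelength band."""


class DimensionError(ValidationError):
    """Mismatched grids or shapes between coupled objects."""


class NoDipError(GmrSpecError):
    """A CCD trace contains no resonance dip deep enough to locate."""


class CalibrationQualityError(GmrSpecError):
    """The raw wavelength -> pixel scan is too non-monotone to calibrate."""


class ExtrapolationError(ValidationError):
    """A lookup was requested outside the calibrated range."""


class InsufficientDataError(ValidationError):
    """Too few points / replicates for the requested statistic."""


class NormalizationError(ValidationError):
    """A run is missing the reference concentration for normalization."""


class PairingError(ValidationError):
    """Two dose-response tables do not share (run, concentration) keys."""


class DegenerateRegressionError(ValidationError):
    """Regression requested on data with zero predictor variance."""


class FormatError(GmrSpecError):
    """A CSV or manifest file violates its declared schema."""


class ConfigError(GmrSpecError):
    """A run configuration failed to parse or validate."""


class DependencyError(GmrSpecError):
    """A pipeline stage is missing an upstream artifact."""
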