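"""Exception hierarchy for the calibration pipeline.

Every stage raises a subclass of :class:`NirspecError` so callers can
distinguish data problems (bad files, degenerate spectra) from programming
errors.
"""


class NirspecError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(NirspecError):
    """The wavelength header of a spectra file disagrees with the expected grid."""


class SpectralParseError(NirspecError):
    """A cell of a spectra or chemistry file could not be parsed."""


class AssemblyError(NirspecError):
    """Spectra and reference chemistry share no sample identifiers."""


class DegenerateInputError(NirspecError):
    """An operator received an input on which it is undefined (e.g. SNV of a constant spectrum)."""


class ScatterFitError(NirspecError):
    """MSC/EMSC multiplicative coefficient is numerically zero."""


class ChainParseError(NirspecError):
    """A pretreatment chain specification contains an unknown or malformed token."""


class ConfigurationError(NirspecError):
    """An operator parameter violates its contract (e.g. even Savitzky-Golay window)."""


class NotFittedError(NirspecError):
    """A reference-dependent transform or model was used before fitting."""


class DegenerateTargetError(NirspecError):
    """The regression target has zero variance."""


class ConvergenceError(NirspecError):
    """NIPALS failed to converge within the iteration budget."""


class SplitError(NirspecError):
    """A random calibration/validation split left one set empty; reseed and retry."""
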