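"""Exception hierarchy for cdvalid.

All cdvalid-specific failures derive from :class:`CDValidError` so callers
can catch the package's errors without masking programming mistakes.
"""


class CDValidError(Exception):
    """Base class for all cdvalid errors."""


class SpectrumParseError(CDValidError):
    """A spectrum or basis-set file could not be parsed."""


class SpectrumInputError(CDValidError):
    """Parsed data violates a spectrum invariant (too short, duplicates...)."""


class GridMismatchError(CDValidError):
    """Two spectra share no usable common wavelength grid."""


class LabelMappingError(CDValidError):
    """Secondary-structure class labels could not be matched between objects."""


class RankDeficiencyError(CDValidError):
    """Basis spectra are (numerically) linearly dependent."""


class ScalingDomainError(CDValidError):
    """A scaling factor is outside its admissible domain (alpha <= 0)."""


class EstimationError(CDValidError):
    """A scaling/validation estimate could not be formed (e.g. all factors
    excluded, anti-correlated prediction)."""


class DegenerateFitError(CDValidError):
    """Deconvolution produced coefficients that cannot be normalized
    (all non-positive)."""


class CalibrationError(CDValidError):
    """Sensitivity-parameter calibration failed (degenerate input)."""


class ConfigurationError(CDValidError):
    """Invalid configuration or distribution parameters."""
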