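"""Exception hierarchy shared across the package."""


class AquaspecError(Exception):
    """Base class for all package errors."""


class ParseError(AquaspecError):
    """A file cell could not be parsed; names the offending row/column."""


class AxisError(AquaspecError):
    """The wavenumber axis is invalid (non-monotonic, duplicated, non-positive)."""


class GridError(AquaspecError):
    """Two spectra do not share a grid, or a grid fails a uniformity requirement."""


class RangeError(AquaspecError):
    """A requested target range falls outside the available source range."""


class WindowError(AquaspecError):
    """A wavenumber window selects no grid points or is ill-formed."""


class PairingError(AquaspecError):
    """A cell spectrum has no resolvable bulk-fluid (PBS) partner."""


class DegenerateFitError(AquaspecError):
    """The least-squares design is too ill-conditioned to identify coefficients."""


class NormalizationError(AquaspecError):
    """Vector normalization requested on an all-zero spectrum."""


class ConfigError(AquaspecError):
    """An invalid configuration value (window parity, step order, fractions)."""


class SingleClassError(AquaspecError):
    """A supervised operation received only one class label."""


class SingularScatterError(AquaspecError):
    """Within-class scatter is singular and no ridge was supplied."""


class StratificationError(AquaspecError):
    """A class has fewer members than the number of cross-validation folds."""
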