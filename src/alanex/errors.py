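"""Exception hierarchy."""


class AlanexError(ValueError):
    """Base class for domain errors raised by alanex."""


class RasterError(AlanexError):
    """Invalid raster content, geometry or units."""


class CalibrationError(AlanexError):
    """Radiometric or cross-sensor calibration cannot be performed."""


class TrajectoryError(AlanexError):
    """Invalid GPS fix series."""


class ExposureError(AlanexError):
    """An exposure estimator cannot be evaluated."""


class InferenceError(AlanexError):
    """A statistical test or model cannot be fitted."""


class ConfigError(AlanexError):
    """Invalid run configuration."""
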