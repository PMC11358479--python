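"""Exception hierarchy used across the package."""


class PaleodispError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PaleodispError, ValueError):
    """A configuration value is inconsistent or out of range."""


class GridMismatchError(ConfigurationError):
    """Fields that must share one grid do not."""


class StabilityError(PaleodispError, RuntimeError):
    """A numerical stability bound (CFL) is violated."""


class FitError(PaleodispError, RuntimeError):
    """Model fitting failed; carries diagnostics in args."""


class UnfittableDataError(FitError):
    """Training data cannot support a fit (e.g. a single class)."""


class DegeneratePredictorError(PaleodispError, ValueError):
    """A predictor has zero variance and cannot be standardized."""


class NormalizationError(PaleodispError, ValueError):
    """A series is constant and cannot be affinely mapped to [0, 1]."""


class UndefinedScoreError(PaleodispError, ValueError):
    """A skill score or AUC is undefined for the given inputs."""
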