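"""Exception types shared across the pipeline stages."""


class UrbanvarError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(UrbanvarError, ValueError):
    """Non-positive or inconsistent array/raster dimensions."""


class EmptyBufferError(UrbanvarError, ValueError):
    """A circular buffer contains no pixel centers."""


class OutOfExtentError(UrbanvarError, ValueError):
    """A sampling point falls outside the raster extent."""


class DomainError(UrbanvarError, ValueError):
    """An input value lies outside its mathematical domain."""


class EmptyDesignError(UrbanvarError, ValueError):
    """A simulation design yields zero observation rows."""


class UndefinedCVError(UrbanvarError, ValueError):
    """A coefficient of variation is undefined (non-positive mean)."""


class DesignRankError(UrbanvarError, ValueError):
    """The fixed-effect design matrix is rank deficient."""


class ConfigError(UrbanvarError, ValueError):
    """Invalid model or pipeline configuration."""


class DegenerateChainError(UrbanvarError, ValueError):
    """A posterior chain is constant; diagnostics are undefined."""


class TermNotFoundError(UrbanvarError, KeyError):
    """A requested fixed-effect term is absent from the fitted model."""


class MissingGroupError(UrbanvarError, ValueError):
    """A requested group has no observations."""


class InsufficientDrawsError(UrbanvarError, ValueError):
    """Too few posterior draws for the requested summary."""


class InsufficientSitesError(UrbanvarError, ValueError):
    """Too few locations remain for the gradient regression."""


class ConstantPredictorError(UrbanvarError, ValueError):
    """A predictor has zero variance and cannot be standardized."""


class CollinearityError(UrbanvarError, ValueError):
    """Gradient predictors are too collinear for a stable regression."""


class AlignmentError(UrbanvarError, ValueError):
    """Posterior draw streams have mismatched lengths or indices."""


class SchemaError(UrbanvarError, ValueError):
    """An input table is missing required columns."""


class UndefinedRankError(UrbanvarError, ValueError):
    """Rank correlation undefined (all-tied input)."""
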