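"""Exception hierarchy for the medsupply pipeline.

Every stage raises a subclass of :class:`MedsupplyError`, so callers (and the
CLI) can distinguish user/data errors from genuine bugs.
"""


class MedsupplyError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MedsupplyError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(MedsupplyError):
    """A panel table violates the required schema."""


class BalanceError(SchemaError):
    """The panel is not balanced (some city misses some year)."""


class MissingDataError(MedsupplyError):
    """Required data (e.g. a deflator year) is absent."""


class DegenerateNormalizationError(MedsupplyError):
    """An indicator is constant across the pooled panel (max == min)."""


class GeometricMeanDomainError(MedsupplyError):
    """Geometric mean requested on non-positive values."""


class DegenerateBandwidthError(MedsupplyError):
    """Automatic KDE bandwidth undefined (zero-spread sample)."""


class UndefinedStatisticError(MedsupplyError):
    """A statistic is undefined for the given input (zero mean, all-zero...)."""


class DegenerateInputError(MedsupplyError):
    """Constant input where spatial statistics require variation."""


class IslandError(MedsupplyError):
    """Row standardization requested but some units have no neighbors."""


class SingularFitError(MedsupplyError):
    """A local GTWR design matrix is rank deficient even after ridge fallback."""
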