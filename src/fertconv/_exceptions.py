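"""Exception hierarchy shared across the package."""


class FertconvError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FertconvError):
    """A required column or indicator is missing from an input table."""


class IntegrityError(FertconvError):
    """Duplicate (country, year, indicator) keys in a panel."""


class ValidationError(FertconvError):
    """Indicator values outside their admissible range.

    Carries the offending (country, year, indicator) keys in ``offenders``.
    """

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class LinkageError(FertconvError):
    """Linking two panels produced an empty intersection."""


class SubgroupSpecError(FertconvError):
    """Unknown subgroup rule or missing metadata column."""


class EmptySampleError(FertconvError):
    """Every candidate regression row was excluded."""


class DegenerateSampleError(FertconvError):
    """Zero variance where standardization requires spread."""


class IdentificationError(FertconvError):
    """Singular design: the regression slope is not identified."""


class InferenceError(FertconvError):
    """Cluster-robust inference is impossible (fewer than 2 clusters)."""


class ConfigError(FertconvError):
    """Invalid simulator or grid configuration."""
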