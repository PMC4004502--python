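"""Exception hierarchy shared across the package."""


class QICompareError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(QICompareError):
    """A configuration value is invalid (e.g. a probability outside [0, 1])."""


class EmptyCohortError(ConfigurationError):
    """A generator was asked to produce a cohort of zero patients."""


class DefinitionError(QICompareError):
    """An indicator definition is malformed or references an unknown item."""


class ConsistencyError(QICompareError):
    """Inputs violate a structural precondition (e.g. selection not in universe)."""


class DegenerateVarianceError(QICompareError):
    """The overlap test variance is exactly zero while the proportions differ."""
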