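"""Exception hierarchy shared across the package."""


class WelfareLCAError(Exception):
    """Base class for all package-specific errors."""


class VocabularyError(WelfareLCAError, ValueError):
    """A categorical value is outside its closed vocabulary."""


class AllocationError(WelfareLCAError, ValueError):
    """Economic allocation is impossible (non-positive reference price)."""


class DegenerateRecordError(WelfareLCAError, ValueError):
    """A production record yields no deadweight / no life-years."""


class NormalizationError(WelfareLCAError, ValueError):
    """Weights or proportions do not sum to one."""


class ConfigurationError(WelfareLCAError, ValueError):
    """An analysis or generator configuration is invalid."""


class StatsInputError(WelfareLCAError, ValueError):
    """A statistical routine received unusable input."""
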