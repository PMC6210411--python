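"""Exception types shared across the package."""


class GaitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GaitError, ValueError):
    """A scenario, smoothing, or run configuration violates an invariant.

    The message names the offending field.
    """


class SchemaError(GaitError, ValueError):
    """A trial file does not conform to the documented CSV schema."""


class TimingError(GaitError, ValueError):
    """Trial timestamps deviate from a uniform sampling grid."""


class InsufficientCyclesError(GaitError, ValueError):
    """Fewer than one complete gait cycle is available for an operation."""


class SampleSizeError(GaitError, ValueError):
    """A statistical routine received fewer observations than it requires."""


class DomainError(GaitError, ValueError):
    """An input lies outside the mathematical domain of a formula."""
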