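"""Exception hierarchy used across the package."""


class MelsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MelsimError):
    """A configuration value or key is invalid."""


class DomainError(MelsimError):
    """A coordinate lies outside the declared domain extent."""


class ContractViolationError(MelsimError):
    """An input violates an operation's contract (e.g. negative density)."""


class IntegrationError(MelsimError):
    """The time integration produced non-finite values."""


class MetricUndefinedError(MelsimError):
    """A metric is undefined for the given input (e.g. zero total mass)."""


class TrajectoryIOError(MelsimError):
    """A trajectory file is missing, partial or corrupt."""
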