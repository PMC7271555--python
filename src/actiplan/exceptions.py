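"""Exception hierarchy used across the package."""


class ActiplanError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ActiplanError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(ActiplanError, ValueError):
    """An input file violates the epoch/summary format contract."""


class InvalidPlanError(ActiplanError, ValueError):
    """A synthetic epoch-day plan violates its invariants."""


class EstimationError(ActiplanError, ValueError):
    """The variance decomposition is not identifiable on this input."""


class DomainError(ActiplanError, ValueError):
    """A planner formula was called outside its mathematical domain."""
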