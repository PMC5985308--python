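"""Exception hierarchy for battery validation and index computation."""


class WshortError(Exception):
    """Base class for all package errors."""


class BatteryValidationError(WshortError):
    """A battery specification violates a structural invariant."""


class SubtestReferenceError(BatteryValidationError):
    """A composite or pool names a subtest the battery does not define."""


class DegenerateCompositeError(WshortError):
    """The implied sum-score variance of a composite is not positive."""


class EstimationError(WshortError):
    """An iterative estimation routine failed to converge."""


class ConfigurationError(WshortError):
    """Inconsistent pipeline configuration (empty pools, bad options...)."""
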