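"""Exception hierarchy shared across the package."""


class SacstratError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SacstratError, ValueError):
    """An argument is outside the physically meaningful domain (e.g. negative eccentricity)."""


class InsufficientDataError(SacstratError, ValueError):
    """Not enough distinct conditions or trials to attempt the requested fit."""


class FitConvergenceError(SacstratError, RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NoSwitchPointError(SacstratError, ValueError):
    """The two strategies never cross on the searched interval."""


class AmbiguousSwitchPointError(SacstratError, ValueError):
    """More than one strategy crossing detected; no single root is returned."""


class UnsupportedEccentricityError(SacstratError, KeyError):
    """A size-sensitivity family was queried at an eccentricity it was not fit at."""


class UnknownConditionError(SacstratError, KeyError):
    """A trial's condition value has no entry in the policy/prediction in use."""


class SchemaError(SacstratError, ValueError):
    """A trial table does not match the expected column schema."""


class ConfigError(SacstratError, ValueError):
    """A run configuration failed validation."""
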