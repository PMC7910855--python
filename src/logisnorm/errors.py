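"""Exception hierarchy used across the package."""


class LogisnormError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LogisnormError, ValueError):
    """A distribution parameter violates its constraint (e.g. lam <= 0)."""


class DomainError(LogisnormError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class DegenerateDataError(LogisnormError, ValueError):
    """The data carry no information for the requested operation
    (constant sample, rank-deficient design, zero IQR, ...)."""


class NumericalError(LogisnormError, RuntimeError):
    """A numerical routine (quadrature, root bracketing) failed to reach
    its tolerance; the message carries a diagnostic."""


class ConvergenceError(LogisnormError, RuntimeError):
    """All optimizer restarts failed to converge."""


class NotNestedError(LogisnormError, ValueError):
    """A likelihood-ratio test was requested for a non-nested model pair."""


class ConfigError(LogisnormError, ValueError):
    """An invalid run configuration or fixture specification."""
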