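"""Exception hierarchy shared across the package."""


class FCMSegError(Exception):
    """Base class for all fcmseg errors."""


class InvalidInputError(FCMSegError, ValueError):
    """Raised when input data violates an operation's preconditions."""


class InvalidConfigError(FCMSegError, ValueError):
    """Raised when a configuration value is out of its allowed range."""


class DegenerateClusterError(FCMSegError, RuntimeError):
    """Raised when a cluster loses all membership mass.

    The fit is not silently re-seeded; callers may retry with a different
    seed so that runs stay reproducible.
    """


class NumericalFailureError(FCMSegError, RuntimeError):
    """Raised when an iteration produces non-finite values."""
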