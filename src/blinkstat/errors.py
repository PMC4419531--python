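"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit status 2 and :class:`DataError`
to exit status 3; everything else is a bug and propagates.
"""


class BlinkstatError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BlinkstatError, ValueError):
    """A model parameter is outside its mathematical domain."""


class DataError(BlinkstatError, ValueError):
    """Input data violate a structural contract (schema, missing cells...)."""


class MissingCellError(DataError):
    """A subject x lag cell required by a balanced design is empty."""


class ConfigError(BlinkstatError, ValueError):
    """A study configuration file or preset name is invalid."""


class FitError(BlinkstatError, RuntimeError):
    """Nonlinear fitting failed to converge or the problem is unidentifiable.

    Carries the per-start diagnostic trace in :attr:`trace` when available.
    """

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []
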