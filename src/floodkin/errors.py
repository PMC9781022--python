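"""Exception taxonomy shared across the package.

CLI exit codes: ConfigError -> 2, DataError/FormatError -> 3.
"""


class FloodkinError(Exception):
    """Base class for all package errors."""


class ParameterError(FloodkinError, ValueError):
    """A function argument violates its contract (sign, ordering, range)."""


class DataError(FloodkinError, ValueError):
    """Input data are insufficient or invalid (too few samples, non-positive times)."""


class StateError(FloodkinError, RuntimeError):
    """An object is not in the state an operation requires (e.g. unescaped run)."""


class ContractError(FloodkinError, RuntimeError):
    """An internal invariant was violated (e.g. negative recorded bias)."""


class IntegrationError(FloodkinError, RuntimeError):
    """The integrator produced a non-finite force/position; message names the step."""


class FormatError(FloodkinError, ValueError):
    """A text file does not conform to the expected dialect."""


class ConfigError(FloodkinError, ValueError):
    """A configuration file is malformed or contains unknown keys."""
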