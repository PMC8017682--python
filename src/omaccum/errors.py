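"""Exception hierarchy shared by all modules.

Three failure classes are distinguished so that callers (and the CLI exit
codes) can react differently to bad user input, inconsistent object shapes,
and numerical breakdown during integration.
"""


class OmaccumError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OmaccumError, ValueError):
    """A parameter, range, or configuration value is out of its admissible set."""


class StructuralError(OmaccumError, ValueError):
    """Object shapes or index sets are mutually inconsistent (e.g. a
    parameter set that does not match its consumption matrix)."""


class NumericalError(OmaccumError, RuntimeError):
    """The integrator produced a non-finite state or otherwise failed."""
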