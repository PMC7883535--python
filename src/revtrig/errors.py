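"""Exception hierarchy shared across the package.

Each class carries the process exit code used by the command-line
interface (0 success, 2 configuration, 3 data, 4 capability).
"""


class RevtrigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RevtrigError):
    """Invalid configuration, scenario or model file."""

    exit_code = 2


class DataError(RevtrigError):
    """Input data unusable: too short, malformed, empty, misaligned."""

    exit_code = 3


class FormatError(DataError):
    """A required column or field is missing or unreadable."""


class CapabilityError(RevtrigError):
    """The request needs a signal or mode the inputs do not provide."""

    exit_code = 4


class SimulationError(RevtrigError):
    """Simulation reached a non-physical state."""

    exit_code = 3
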