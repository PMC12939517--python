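"""Exception hierarchy for coopgate.

The CLI maps these onto exit codes: invalid parameters -> 2,
insufficient data -> 3, I/O problems -> 4.
"""


class CoopgateError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CoopgateError, ValueError):
    """A model or metric parameter is outside its physically valid range."""


class InsufficientDataError(CoopgateError, ValueError):
    """Not enough data points / windows / replicates for the requested estimate."""


class UnsupportedCapacityError(CoopgateError, ValueError):
    """A current level exceeds the supported 0..6 histogram range."""


class InvalidRadiusError(InvalidParameterError):
    """Sample-entropy similarity radius is zero or negative (e.g. constant series)."""


class EventTableParseError(CoopgateError, ValueError):
    """An idealized event table could not be parsed; message names the line."""
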