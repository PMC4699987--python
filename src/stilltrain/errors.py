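"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`StilltrainError`
so callers (and the CLI) can distinguish user/input mistakes from genuine bugs.
"""


class StilltrainError(Exception):
    """Base class for all package errors."""


class ConfigError(StilltrainError, ValueError):
    """Invalid configuration value, unknown key, or blind detector."""


class BoundsError(StilltrainError, ValueError):
    """A region or blob falls outside the frame it applies to."""


class ShapeError(StilltrainError, ValueError):
    """Mismatched frame/mask dimensions."""


class InputError(StilltrainError, ValueError):
    """Structurally invalid input (too few frames, unsorted samples, ...)."""


class SessionStateError(StilltrainError, RuntimeError):
    """Operation applied to a session in a state that forbids it."""


class LogFormatError(StilltrainError, ValueError):
    """A record cannot be serialized (unknown status)."""


class LogParseError(StilltrainError, ValueError):
    """A log file line cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno
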