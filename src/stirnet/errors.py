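"""Exception hierarchy shared across the pipeline."""


class StirNetError(Exception):
    """Base class for all package errors."""


class InvalidInputError(StirNetError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(StirNetError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class ConfigurationError(StirNetError):
    """A model or pipeline configuration is incomplete or inconsistent."""


class VolumeIOError(StirNetError, IOError):
    """A volume file could not be read or written; the message carries the path."""
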