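"""Exception types shared across the pipeline."""


class AutoplotError(Exception):
    """Base class for all hard errors raised by this package."""


class DialectError(AutoplotError):
    """Input file violates the column contract of its declared dialect."""


class ValidationError(AutoplotError):
    """Sample design, config or value-level validation failed."""


class StageError(AutoplotError):
    """A pipeline stage failed; the message names the stage."""
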