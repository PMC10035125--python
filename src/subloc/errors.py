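"""Exception types shared across the package."""


class SublocError(ValueError):
    """Base class for validation and format errors raised by this package."""


class ValidationError(SublocError):
    """Input violates a documented contract (alphabet, labels, config)."""


class FormatError(SublocError):
    """A file does not conform to its declared dialect."""


class LengthError(SublocError):
    """Sequence too short for the requested encoding."""
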