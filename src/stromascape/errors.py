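"""Exception types shared across the package."""


class FormatError(ValueError):
    """A table violates the expected file format (duplicate ids, bad columns)."""


class DegenerateInputError(ValueError):
    """Input is schema-valid but numerically unusable (zero housekeeping signal,
    zero-variance anchor, single-class outcome, ...)."""


class ConfigurationError(ValueError):
    """A required piece of run configuration is missing or inconsistent."""
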