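"""Exception hierarchy shared across the pipeline."""


class XiEscapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(XiEscapeError, ValueError):
    """A file does not conform to its declared dialect (missing column, bad line)."""


class IntegrityError(XiEscapeError, ValueError):
    """Parsed data violates an invariant (duplicates, negative counts, ...)."""


class ConfigurationError(XiEscapeError, ValueError):
    """A requested condition, rule or option does not exist."""


class InsufficientDataError(XiEscapeError, ValueError):
    """Not enough observations for the requested computation."""
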