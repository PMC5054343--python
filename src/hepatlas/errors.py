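"""Exception hierarchy shared across the package."""


class HepatlasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HepatlasError):
    """A file could not be parsed (malformed header, bad field count, ...)."""


class ValidationError(HepatlasError):
    """Parsed content violates a domain invariant (negative abundance,
    duplicate identifier, self-loop edge, ...)."""


class GenerationError(HepatlasError):
    """The synthetic-data generator was given an infeasible configuration or
    failed its internal planted-truth self-check."""
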