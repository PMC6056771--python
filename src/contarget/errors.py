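"""Exception types shared across the package."""


class ContargetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ContargetError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(ContargetError):
    """Input data violates a structural invariant (duplicate ids, bad bounds, ...)."""


class ConsistencyError(ContargetError):
    """An internal numerical certificate failed (e.g. PBH verification)."""
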