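"""Exception hierarchy shared across the package."""


class GscMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(GscMorphError, ValueError):
    """Invalid user input: bad spec, malformed table, out-of-range parameter."""


class FormatError(ValidationError):
    """A file on disk does not match the expected format."""


class GenerationError(ValidationError):
    """A synthetic spec cannot be rendered (e.g. geometry leaves the image)."""


class InternalConsistencyError(GscMorphError, RuntimeError):
    """A structural invariant that should hold by construction was violated."""
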