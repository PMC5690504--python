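"""Exception hierarchy shared across the package."""


class RespmarkError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RespmarkError, ValueError):
    """A configuration or function parameter violates its contract."""


class DegenerateInputError(RespmarkError, ValueError):
    """Input data is degenerate (constant channel, empty set, ...)."""


class AlignmentError(RespmarkError, ValueError):
    """Two series that must share a time grid or length do not."""


class SchemaError(RespmarkError, ValueError):
    """A file or record does not match the expected schema."""


class FormatError(RespmarkError, ValueError):
    """A file is structurally malformed (empty, non-uniform grid, ...)."""
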