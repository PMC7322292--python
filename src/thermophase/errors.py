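"""Exception types shared across the package."""


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class FormatError(ValueError):
    """An input violates a structural requirement (e.g. non-uniform time grid)."""


class GridAlignmentError(ValueError):
    """Two series that must share a time grid do not."""


class DegenerateSignalError(ValueError):
    """A signal is constant / all-zero where variation is required."""


class ParameterError(ValueError):
    """A numeric parameter is outside its valid range."""


class LengthError(ValueError):
    """A record is too short for the requested operation."""
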