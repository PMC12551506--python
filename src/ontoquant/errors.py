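"""Exception hierarchy shared across the package."""


class OntoquantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OntoquantError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(OntoquantError, ValueError):
    """A file does not conform to its declared dialect or schema."""


class SchemeCombinationError(OntoquantError):
    """Raised when quantization scales cannot be factored out of an
    integer accumulation, i.e. the operand schemes are non-dequantizable
    in combination (per-channel activation scales varying along the
    contraction axis)."""
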