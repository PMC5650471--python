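"""Exception types shared across the package."""


class MethyldynError(ValueError):
    """Base class for all validation and domain errors raised here."""


class DomainError(MethyldynError):
    """A physical quantity is outside its mathematically valid domain."""


class InputError(MethyldynError):
    """An input dataset violates a structural precondition."""


class FormatError(MethyldynError):
    """A file does not conform to the expected tabular schema."""
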