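"""Exception types shared across the package."""


class IrcutError(Exception):
    """Base class for all package-specific errors."""


class DomainError(IrcutError, ValueError):
    """An input value lies outside the mathematical domain of a formula."""


class DegenerateInputError(IrcutError, ValueError):
    """Input is structurally unusable (constant variable, empty group, ...)."""


class SchemaError(IrcutError, ValueError):
    """Tabular input does not conform to the documented cohort schema."""


class SpecValidationError(IrcutError, ValueError):
    """A simulation specification violates its invariants."""
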