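"""Exception hierarchy shared across the package."""

__all__ = [
    "OatmetError",
    "SchemaError",
    "IntegrityError",
    "TraitNotFoundError",
    "DomainError",
    "DegenerateInputError",
    "ConfigError",
    "ValidationError",
]


class OatmetError(Exception):
    """Base class for all package errors."""


class SchemaError(OatmetError):
    """Input file does not provide the required columns."""


class IntegrityError(OatmetError):
    """Input violates a structural invariant (e.g. duplicate keys)."""


class TraitNotFoundError(OatmetError, KeyError):
    """Requested trait is not present in the table."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class DomainError(OatmetError, ValueError):
    """Argument outside the mathematical domain of a formula."""


class DegenerateInputError(OatmetError):
    """Input is formally valid but makes the requested quantity undefined."""


class ConfigError(OatmetError):
    """Invalid scenario or run configuration."""


class ValidationError(OatmetError):
    """Run configuration references resources that do not exist."""
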