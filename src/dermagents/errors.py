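"""Exception types shared across the package."""


class DermagentsError(Exception):
    """Base class for package errors."""


class DomainError(DermagentsError, ValueError):
    """An input violates a documented domain precondition."""


class ConfigurationError(DermagentsError, ValueError):
    """A configuration value is invalid or inconsistent."""


class ContractError(DermagentsError, RuntimeError):
    """An API was called in a way its contract forbids (caller bug)."""
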