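"""Exception hierarchy shared across the pipeline stages."""


class ErvScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ErvScreenError, ValueError):
    """A user-supplied configuration value is out of range or inconsistent."""


class DataError(ErvScreenError, ValueError):
    """Input data violate a documented schema or invariant."""


class ContractViolation(ErvScreenError, ValueError):
    """An operation was called outside its documented preconditions."""
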