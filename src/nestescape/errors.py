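"""Exception types shared across the package."""


class NestescapeError(Exception):
    """Base class for all package errors."""


class FormatError(NestescapeError, ValueError):
    """A file or table does not have the expected structure."""


class DataError(NestescapeError, ValueError):
    """Input values violate an invariant (range, monotonicity, emptiness...)."""


class ConfigError(NestescapeError, ValueError):
    """A configuration value is invalid or inconsistent."""
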