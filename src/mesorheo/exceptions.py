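"""Exception types shared across the package."""


class MesorheoError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MesorheoError):
    """A configuration value is missing, inconsistent, or out of range."""


class SchemaError(MesorheoError):
    """An input table violates the expected schema (columns, ordering, duplicates)."""
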