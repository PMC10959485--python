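"""Exception hierarchy shared across the package."""


class ClineselError(Exception):
    """Base class for all package errors."""


class SchemaError(ClineselError):
    """A required column is missing or a column mapping is invalid."""


class IntegrityError(ClineselError):
    """Duplicate keys or unresolvable foreign references in a trial table."""


class ConfigError(ClineselError):
    """Invalid simulation or run configuration."""


class DataError(ClineselError):
    """Input data cannot support the requested computation."""
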