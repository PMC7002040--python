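"""Exception hierarchy shared across the package.

The CLI maps :class:`InputError` to exit code 2 and :class:`ConfigError`
to exit code 3; library code raises them directly.
"""


class RibomitoError(Exception):
    """Base class for all package-specific errors."""


class InputError(RibomitoError):
    """Malformed or inconsistent input data (files, tables, vectors)."""


class ConfigError(RibomitoError):
    """Invalid configuration or parameter value; names the offending field."""
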