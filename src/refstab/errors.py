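"""Exception hierarchy.

``InputError`` covers malformed or inconsistent input data (CLI exit code 1);
``ConfigError`` covers bad options or parameters (CLI exit code 2).
"""


class RefstabError(Exception):
    """Base class for all package errors."""


class InputError(RefstabError, ValueError):
    """Malformed, inconsistent, or insufficient input data."""


class ConfigError(RefstabError, ValueError):
    """Invalid configuration or option value."""
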