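"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to 3.
"""


class MethylQuadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MethylQuadError, ValueError):
    """Invalid configuration or parameter value."""


class DataError(MethylQuadError, ValueError):
    """Malformed or inconsistent input data."""
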