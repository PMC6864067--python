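"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError to 3.
"""


class AssortMRError(Exception):
    """Base class for package errors."""


class ConfigError(AssortMRError):
    """Invalid configuration: impossible variance budget, bad ranges, missing stages."""


class DataError(AssortMRError):
    """Invalid or malformed input data: bad dosages, malformed VCF/CSV, degenerate designs."""
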