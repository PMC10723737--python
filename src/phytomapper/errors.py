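"""Exception hierarchy."""


class PhytomapperError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhytomapperError, ValueError):
    """Invalid configuration or mismatched inputs."""


class FormatError(PhytomapperError, ValueError):
    """Malformed input file (orthogroup table, GMT, metadata ...)."""
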