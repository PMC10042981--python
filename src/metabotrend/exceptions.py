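"""Exception hierarchy shared across the pipeline stages."""


class MetabotrendError(Exception):
    """Base class for all package errors."""


class ValidationError(MetabotrendError, ValueError):
    """A table, matrix or parameter failed a structural precondition."""


class ConfigError(MetabotrendError, ValueError):
    """The pipeline configuration is malformed (CLI exit code 2)."""


class DataError(MetabotrendError, ValueError):
    """Input data violate a contract at run time (CLI exit code 3)."""
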