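"""Exception types shared across the package."""


class TailshiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TailshiftError):
    """A parameter or configuration value is invalid."""


class ValidationError(TailshiftError):
    """Input data violate a structural contract (bad coordinates, schema, ...)."""


class PipelineError(TailshiftError):
    """A pipeline stage failed; the message names the stage."""
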