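"""Exception hierarchy used across the pipeline."""


class AlffPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AlffPipeError):
    """A configuration is internally inconsistent or physically impossible."""


class InvalidInputError(AlffPipeError, ValueError):
    """An input violates a documented precondition."""


class FormatError(AlffPipeError):
    """A file could not be parsed as the expected on-disk format."""


class NumericalError(AlffPipeError):
    """A numerical procedure failed (rank deficiency, non-convergence, ...)."""
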