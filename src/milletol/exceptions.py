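"""Exception hierarchy shared across the pipeline stages."""


class MilletolError(Exception):
    """Base class for all package errors."""


class SchemaError(MilletolError):
    """Input table does not have the required columns/labels/shape."""


class DegenerateInputError(MilletolError):
    """Input is structurally valid but numerically unusable
    (constant column, zero column total, singular matrix, ...)."""


class ConfigError(MilletolError):
    """Invalid option or parameter value."""
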