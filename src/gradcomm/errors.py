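"""Exception hierarchy shared across the package."""


class GradcommError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GradcommError, ValueError):
    """A required column is missing or a schema mapping is unresolvable."""


class ValidationError(GradcommError, ValueError):
    """Row-level input data failed validation."""


class ParameterError(GradcommError, ValueError):
    """An operation was called with an out-of-range parameter."""


class InputError(GradcommError, ValueError):
    """Input stream/table is empty or otherwise unusable."""


class ConfigError(GradcommError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""
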