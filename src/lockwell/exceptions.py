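"""Exception hierarchy for the lockwell pipeline."""


class LockwellError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LockwellError, ValueError):
    """An invalid simulation or run configuration."""


class SchemaError(LockwellError, ValueError):
    """A predictor schema inconsistency (unknown level, missing column...)."""


class ValidationError(LockwellError, ValueError):
    """Invalid data values (out-of-range items, non-finite entries...)."""
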