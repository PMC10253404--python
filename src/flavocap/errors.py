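"""Exception types shared across the pipeline."""


class FlavocapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FlavocapError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(FlavocapError):
    """An input table is missing required columns or violates the declared schema."""


class ValidationError(FlavocapError):
    """A record-level violation (bad value, unknown accession, duplicate id)."""
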