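"""Exception types shared across the pipeline."""


class LncsigError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LncsigError):
    """A parameter, column mapping, or format choice is invalid."""


class DataError(LncsigError):
    """Input data violate a contract (duplicates, missing labels, bad values)."""
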