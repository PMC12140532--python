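"""Exception hierarchy shared across the package."""


class WristGaitError(Exception):
    """Base class for all package errors."""


class FormatError(WristGaitError):
    """A file does not conform to the expected on-disk schema."""


class DataError(WristGaitError):
    """Input data violate a semantic precondition (ordering, overlap, NaN...)."""


class ConfigError(WristGaitError):
    """A configuration value is outside its admissible range."""
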