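"""Typed exception hierarchy shared by all modules."""


class LocorespError(Exception):
    """Base class for every error raised by this package."""


class FormatError(LocorespError):
    """A file does not follow the expected on-disk dialect."""


class ValidationError(LocorespError):
    """Data violates a domain invariant (non-finite sample, out-of-range value...)."""


class ParameterError(LocorespError):
    """A configuration or call parameter is out of its admissible range."""


class ConfigurationError(ParameterError):
    """A required configuration entry (e.g. a bodypart) is missing."""
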