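"""Exception hierarchy."""


class MalinesError(Exception):
    """Base class for package errors."""


class ConfigError(MalinesError, ValueError):
    """A configuration value is non-finite or out of range."""


class FormatError(MalinesError, ValueError):
    """A file does not conform to the expected format."""


class UnscorableSiteError(MalinesError):
    """A site could not be scored by the probabilistic model."""
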