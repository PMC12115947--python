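"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file could be opened but does not conform to the expected layout."""


class ParameterError(ValueError):
    """A configuration value is outside its valid domain."""


class ConfigurationError(ValueError):
    """A required input (e.g. a photosensor channel) is missing."""


class AveragingError(ValueError):
    """Too few retained epochs to form the requested average."""
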