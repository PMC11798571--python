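"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration or construction parameter is invalid or inconsistent."""


class DataError(ValueError):
    """Input data violate a precondition of an operation."""
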