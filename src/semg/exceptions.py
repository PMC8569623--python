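"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """An invalid parameter combination (band edges, sampling rate, basis...)."""


class DimensionError(ValueError):
    """Array shapes incompatible with the requested operation."""


class EmptyInputError(ValueError):
    """Input too short or empty for the requested operation."""
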