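"""Shared exception types."""


class ConfigError(ValueError):
    """A configuration value is invalid or inconsistent."""


class DataError(ValueError):
    """Input data violates a structural expectation (duplicates, bad keys...)."""
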