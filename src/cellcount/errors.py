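"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent or names an unknown option."""


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for the given data (e.g. zero variance)."""
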