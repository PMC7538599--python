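"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An input configuration violates its invariants."""


class InsufficientDataError(ValueError):
    """Too few samples or dwells to run the requested estimator."""
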