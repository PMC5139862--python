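"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration object violates its invariants."""


class DomainError(ValueError):
    """An input is outside the domain an operation is defined on."""
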