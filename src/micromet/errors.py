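"""Exception types shared across the simulator."""


class ConfigurationError(ValueError):
    """An invalid parameter value or inconsistent configuration."""


class OutOfDomainError(ValueError):
    """A position outside the simulated tissue patch."""


class StaleReferenceError(RuntimeError):
    """An interaction referenced a cell that was already removed from the world."""
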