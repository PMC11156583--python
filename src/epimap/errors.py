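"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or analysis configuration violates its invariants."""


class ParameterError(ValueError):
    """An analysis parameter is outside its admissible range."""


class InputError(ValueError):
    """Input data do not satisfy an operation's preconditions."""
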