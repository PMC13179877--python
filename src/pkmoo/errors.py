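"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A search space, scenario or algorithm config is invalid or infeasible."""


class NumericalError(RuntimeError):
    """A numerical routine failed in a way that should be reported, not raised
    through the search loop (fit wrappers convert this into non-convergence)."""
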