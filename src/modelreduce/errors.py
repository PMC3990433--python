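"""Exception hierarchy for the model-reduction toolkit."""


class ModelReduceError(Exception):
    """Base class for all package errors."""


class SpecError(ModelReduceError):
    """Model specification is malformed (unknown symbol, bad schema, ...)."""


class CycleError(SpecError):
    """Update rules contain a same-day dependency cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "intra-step dependency cycle: " + " -> ".join(self.cycle + [self.cycle[0]])
        )


class ExpressionError(SpecError):
    """An update-rule expression failed to parse or used a forbidden construct."""


class SimulationError(ModelReduceError):
    """A simulation produced a non-finite value or failed numerically."""

    def __init__(self, message, variable=None, day=None, site=None):
        self.variable = variable
        self.day = day
        self.site = site
        super().__init__(message)


class CoverageError(ModelReduceError):
    """An observation could not be matched to a model prediction."""


class DegenerateDataError(ModelReduceError):
    """Observed values carry no variance in the requested scope."""


class LookupError_(ModelReduceError):
    """A name was not found (variable, stream, site...)."""


class ParameterError(ModelReduceError):
    """An argument is out of its valid domain."""


class ConfigError(ModelReduceError):
    """A reduction or fixture configuration is invalid."""
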