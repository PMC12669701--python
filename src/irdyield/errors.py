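"""Exception types shared across the pipeline stages."""


class InvalidInputError(ValueError):
    """A record or argument violates the contract of an operation."""


class ConfigurationError(ValueError):
    """Inconsistent configuration, e.g. a variant in a gene without a model."""


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for the given data
    (empty stratum, no phased pairs, no usable loci, ...)."""


class FitError(RuntimeError):
    """A model fit failed to converge or the data are degenerate.

    Carries the iteration trace so the failure can be diagnosed.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
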