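"""Exception hierarchy for condde.

All condde-specific failures derive from :class:`CondDEError` so callers
can catch the package's errors with a single except clause.
"""


class CondDEError(Exception):
    """Base class for all condde errors."""


class NetworkParseError(CondDEError):
    """A network file line could not be parsed; message names the line number."""


class CycleError(CondDEError):
    """A directed cycle was found where a DAG is required."""

    def __init__(self, witness):
        self.witness = tuple(witness)
        super().__init__(
            "graph contains a directed cycle: " + " -> ".join(self.witness)
        )


class DegenerateResponseError(CondDEError):
    """The response variable has zero sample variance (or a perfect fit)."""


class RankDeficiencyError(CondDEError):
    """The regression design matrix is rank deficient."""


class InsufficientDFError(CondDEError):
    """Residual degrees of freedom below one; the fit is not identifiable."""


class NestingError(CondDEError):
    """Deviance comparison requested for models that are not nested."""


class SpecValidationError(CondDEError):
    """A simulation spec violates its invariants; message lists all violations."""
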