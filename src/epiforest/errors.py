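"""Exception hierarchy for the epiforest pipeline."""


class EpiforestError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EpiforestError, ValueError):
    """A caller-supplied argument violates a precondition."""


class DegenerateInputError(EpiforestError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero total count,
    constant phenotype) so the requested quantity is undefined."""


class DegenerateModelError(EpiforestError):
    """An expression tree produced a constant raw output, so no binary
    phenotype with the requested case fraction can be derived from it."""


class CorruptTreeError(EpiforestError):
    """An expression tree references an unknown operator or is malformed."""


class SimulationFailureError(EpiforestError):
    """The genetic-programming run could not produce any non-degenerate
    individual."""


class ParseError(EpiforestError, ValueError):
    """A data file could not be parsed; the message names the location."""


class UndefinedScoreError(EpiforestError, ValueError):
    """A performance score is undefined for the given labels (e.g. balanced
    accuracy with a single observed class)."""
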