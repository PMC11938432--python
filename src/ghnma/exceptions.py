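"""Exception hierarchy for the NMA pipeline.

Errors are split by pipeline stage so the CLI can map them to distinct,
named exit codes (validation / feasibility / convergence).
"""


class GhnmaError(Exception):
    """Base class for all package errors."""


class ParseError(GhnmaError):
    """A CSV cell or row could not be parsed; message names the row."""


class ValidationError(GhnmaError):
    """Input data violate a type invariant (e.g. events > n)."""


class FeasibilityError(GhnmaError):
    """An analytic scenario fails a feasibility rule, e.g. fewer than two
    studies report the outcome of interest at the analysis time point."""


class DisconnectedNetworkError(FeasibilityError):
    """The evidence network is not a single connected component."""


class ConvergenceError(GhnmaError):
    """MCMC diagnostics failed the convergence gate (R-hat / ESS)."""


class SingularNetworkError(GhnmaError):
    """The design matrix of the frequentist oracle is rank deficient."""
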