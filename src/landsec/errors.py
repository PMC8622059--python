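"""Exception hierarchy shared across the package.

Validation problems (bad schemas, broken invariants) derive from
:class:`ValidationError`; numerical failures (non-convergence) derive from
:class:`NumericError`.  The CLI maps them to exit codes 1 and 2.
"""

from __future__ import annotations


class LandsecError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LandsecError, ValueError):
    """Input violates a documented precondition or invariant."""


class SchemaError(ValidationError):
    """A tabular input does not match the expected schema."""


class ConsistencyError(ValidationError):
    """A cross-record consistency rule is violated.

    When raised for a pairwise judgment matrix that fails the consistency
    test, the offending :class:`~landsec.ahp_weights.ConsistencyReport` is
    attached as ``report``.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class UnsupportedOrderError(ValidationError):
    """Matrix order outside the supported random-index table."""


class NumericError(LandsecError, RuntimeError):
    """An iterative numerical procedure failed to converge."""


class SaatyScaleWarning(UserWarning):
    """Judgment-matrix entries fall outside the 1/9..9 elicitation scale."""
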