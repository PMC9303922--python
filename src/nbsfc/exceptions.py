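"""Error types shared across the pipeline.

Every stage raises one of these rather than a bare ``ValueError`` so that
callers (and the CLI driver) can attach stage context and exit cleanly.
"""


class NbsfcError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NbsfcError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateConditionError(NbsfcError):
    """A condition has no usable temporal weight (e.g. fully censored)."""


class ZeroVarianceError(NbsfcError):
    """A node or edge has zero (weighted) variance where variance is required."""


class OutOfDomainError(NbsfcError):
    """A value lies outside the mathematical domain of a transform (|r| >= 1)."""
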