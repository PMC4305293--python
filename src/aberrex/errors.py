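"""Typed exceptions raised across the package."""


class AberrexError(Exception):
    """Base class for all package errors."""


class FormatError(AberrexError):
    """Malformed input file (ragged rows, bad field counts, non-numeric cells)."""


class DuplicateIdError(FormatError):
    """Duplicated gene or sample identifier where uniqueness is required."""


class ValidationError(AberrexError):
    """Inputs violate an operation's preconditions."""


class SingularCovarianceError(AberrexError):
    """Covariance estimation failed (constant gene, rank deficiency)."""

    def __init__(self, message: str, genes: list[str] | None = None):
        super().__init__(message)
        self.genes = genes or []


class DegenerateInputError(AberrexError):
    """Too few samples relative to dimensions, empty groups, etc."""
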