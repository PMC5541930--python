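"""Exception hierarchy for patchtraits."""


class PatchTraitsError(Exception):
    """Base class for all package errors."""


class GridParseError(PatchTraitsError):
    """A grid file could not be parsed; the message names the offending line."""


class ValidationError(PatchTraitsError):
    """An input violates a structural invariant (codes, shapes, duplicates)."""


class AlignmentError(PatchTraitsError):
    """Row/column labels of the R, L, Q or covariate tables do not match."""


class DegenerateInputError(PatchTraitsError):
    """An input is structurally valid but statistically degenerate
    (constant column, all-zero plot, empty class)."""
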