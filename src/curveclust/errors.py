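"""Exception hierarchy used across the package."""


class CurveClustError(Exception):
    """Base class for all curveclust errors."""


class FormatError(CurveClustError):
    """Input file does not match the expected tabular layout."""


class EmptyInputError(CurveClustError):
    """An operation received no usable data."""


class InfeasibleBasisError(CurveClustError):
    """Requested spline basis dimension cannot be supported by the data."""


class FitFailureError(CurveClustError):
    """All EM starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class DegenerateClusteringError(CurveClustError):
    """A cluster-validity index is undefined for this partition
    (e.g. two clusters share an identical mean curve)."""
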