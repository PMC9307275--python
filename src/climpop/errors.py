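"""Exception hierarchy shared across the pipeline stages."""


class ClimpopError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ClimpopError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ClimpopError, ValueError):
    """Input is structurally valid but carries no usable signal
    (constant series, all-zero anomalies, identical coordinates...)."""


class InvalidStateError(ClimpopError, RuntimeError):
    """Operation called out of order (e.g. growth rates before filtering)."""


class MissingTaxonError(ClimpopError, KeyError):
    """Species names absent from the phylogeny after synonym mapping."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "taxa not found in tree after synonym mapping: " + ", ".join(self.missing)
        )


class NumericFailureError(ClimpopError, ArithmeticError):
    """A numerical requirement failed (e.g. covariance not PSD)."""
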