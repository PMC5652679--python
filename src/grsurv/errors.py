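"""Exception hierarchy used across the pipeline."""


class GrsurvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GrsurvError):
    """Input data violates a documented invariant (bad cell value, bad range)."""


class VcfParseError(GrsurvError):
    """A VCF could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class UnsupportedRecordError(GrsurvError):
    """VCF records outside the supported dialect (multiallelic, indels)."""

    def __init__(self, records: list[str]):
        self.records = records
        super().__init__(
            "unsupported (multiallelic or non-SNP) records: " + ", ".join(records)
        )


class DuplicateVariantError(GrsurvError):
    """The same variant identifier occurs more than once in a dataset."""


class AlignmentError(GrsurvError):
    """Sample sets of two inputs do not match."""


class OrientationError(GrsurvError):
    """A score-model effect allele is not one of the variant's two alleles."""


class EmptyModelError(GrsurvError):
    """A risk-score model with no entries reached the scoring stage."""


class CollinearityError(GrsurvError):
    """Two model covariates are (numerically) linearly dependent."""


class ConvergenceError(GrsurvError):
    """An iterative fit failed to converge and no usable estimate exists."""
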