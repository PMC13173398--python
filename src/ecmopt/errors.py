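"""Exception types shared across the package."""


class EcmoptError(Exception):
    """Base class for all package errors."""


class InvalidBoundsError(EcmoptError, ValueError):
    """Factor bounds are non-positive or inverted."""


class ConfigError(EcmoptError, ValueError):
    """A configuration value is inconsistent or out of range."""


class ValidationError(EcmoptError, ValueError):
    """An input table violates its contract (e.g. non-integer raw counts)."""


class SizeFactorError(EcmoptError, ValueError):
    """No gene is positive in all samples; median-of-ratios size factors undefined."""


class NoReferenceError(EcmoptError, ValueError):
    """Every candidate reference gene was excluded (mean <= 0)."""


class DivisionGuardError(EcmoptError, ValueError):
    """The reference gene is non-positive in at least one sample."""


class GroupingError(EcmoptError, ValueError):
    """A replicate group is empty or a sample is unmapped."""


class SingularFitError(EcmoptError, ValueError):
    """The design matrix is rank deficient for the requested terms."""

    def __init__(self, collinear_terms):
        self.collinear_terms = tuple(collinear_terms)
        super().__init__(
            "rank-deficient basis; collinear terms: " + ", ".join(self.collinear_terms)
        )


class UndefinedFitError(EcmoptError, ValueError):
    """Too few observations for the number of coefficients."""


class AlignmentError(EcmoptError, ValueError):
    """Expression columns do not align with design runs."""


class SpecError(EcmoptError, ValueError):
    """An ObjectiveSpec is malformed (length mismatch, bad weights...)."""


class EmptySelectionError(EcmoptError, ValueError):
    """No candidate composition satisfies the control-selection constraints."""

    def __init__(self, message, gap_range=None, cheb_range=None):
        self.gap_range = gap_range
        self.cheb_range = cheb_range
        super().__init__(message)


class UndefinedScoreError(EcmoptError, ValueError):
    """A score (e.g. SFI) is undefined for the given table."""


class GeneSetError(EcmoptError, ValueError):
    """A required gene set is empty or entirely absent from the matrix."""


class PairingError(EcmoptError, ValueError):
    """A condition score has no matching per-donor baseline."""


class InsufficientDataError(EcmoptError, ValueError):
    """Too few samples for the requested analysis."""


class ParseError(EcmoptError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
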