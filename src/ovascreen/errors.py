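"""Exception hierarchy shared across the pipeline stages."""


class OvascreenError(Exception):
    """Base class for all package errors."""


class ConfigError(OvascreenError, ValueError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(OvascreenError, ValueError):
    """Input table violates the documented column schema."""


class ReferentialIntegrityError(SchemaError):
    """A sample references a subject_id absent from the subjects table."""


class ValidationError(OvascreenError, ValueError):
    """A value violates a domain invariant (e.g. non-positive concentration)."""


class AlignmentError(OvascreenError):
    """A control cannot be temporally aligned to its matched case."""


class BaselineUnusableError(OvascreenError):
    """Subject has no samples eligible for baseline estimation.

    Carries ``subject_id`` so callers can flag/exclude the subject.
    """

    def __init__(self, subject_id: str):
        self.subject_id = subject_id
        super().__init__(f"no usable baseline for subject {subject_id!r}")


class FittingError(OvascreenError):
    """Maximum-likelihood fit failed (non-convergence or degeneracy)."""


class SeparationError(FittingError):
    """Perfect separation detected: the MLE does not exist."""
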