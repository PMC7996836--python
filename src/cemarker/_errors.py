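"""Package-wide exception types."""


class CEMarkerError(Exception):
    """Base class for all package errors."""


class RecordingError(CEMarkerError):
    """Invalid or unreadable EEG recording."""


class CohortError(CEMarkerError):
    """Questionnaire/cohort-selection failure."""


class EstimatorError(CEMarkerError):
    """Information-theoretic estimator precondition failure."""


class SyntheticError(CEMarkerError):
    """Synthetic-data specification failure."""


class AnalysisError(CEMarkerError):
    """RSA / classification / pipeline stage failure."""
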