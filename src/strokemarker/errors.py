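"""Exception hierarchy for cohort validation and statistical degeneracies."""


class StrokemarkerError(Exception):
    """Base class for all package errors."""


class CohortSchemaError(StrokemarkerError):
    """The cohort file is missing a required column or has a malformed header."""


class RowValidationError(StrokemarkerError):
    """A row holds a non-parseable or out-of-range value.

    Carries ``patient_id`` and ``field`` so callers can locate the offending cell.
    """

    def __init__(self, message: str, patient_id: str | None = None, field: str | None = None):
        super().__init__(message)
        self.patient_id = patient_id
        self.field = field


class CohortValidationError(StrokemarkerError):
    """Cohort-level invariant violated (duplicate ids, empty cohort, ...)."""


class ParameterError(StrokemarkerError):
    """Invalid simulation parameters (e.g. non positive-definite copula matrix)."""


class CalibrationError(StrokemarkerError):
    """Intercept calibration failed to converge; message carries bracket diagnostics."""


class SeparationError(StrokemarkerError):
    """Complete or quasi-complete separation in a logistic fit."""


class CollinearityError(StrokemarkerError):
    """Singular design matrix; message names the dependent columns."""


class DegenerateBinningError(StrokemarkerError):
    """Too few distinct values to form quantile bins."""


class DegenerateLabelsError(StrokemarkerError):
    """Only one outcome class present where both are required."""


class DegenerateComparisonError(StrokemarkerError):
    """AUC-difference variance is numerically zero; no valid z-statistic exists."""


class DegenerateTableError(StrokemarkerError):
    """Reclassification table has an empty event or non-event stratum."""


class DegenerateGroupError(StrokemarkerError):
    """A survival group is empty or no deaths occurred overall."""
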