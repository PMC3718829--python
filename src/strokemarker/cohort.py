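"""Cohort domain types, CSV input/output, validation and outcome dichotomization.

A cohort is one row per acute ischemic stroke patient: admission covariates
(age in years, NIHSS score, recanalization therapy), the plasma biomarker
concentration (MR-proADM, nmol/l), the modified Rankin Scale at day 90, the
90-day death indicator and follow-up time in days. The 90-day functional
outcome is dichotomized into favourable (mRS 0-2) and unfavourable (mRS 3-6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortSchemaError, CohortValidationError, RowValidationError

logger = logging.getLogger(__name__)

#: Columns every cohort file must name (case-insensitive header match).
REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "nihss",
    "recanalization",
    "mr_proadm",
    "mrs_90",
    "died_90",
    "followup_days",
)

#: Categorical columns carried through but never computed on.
OPTIONAL_COLUMNS = ("sex", "hypertension", "atrial_fibrillation", "ocsp", "ccs")

#: Minimum admission NIHSS under the strict eligibility rule ("more than 3").
ELIGIBILITY_MIN_NIHSS = 4

STUDY_HORIZON_DAYS = 90


@dataclass(frozen=True)
class OutcomeLabel:
    """Dichotomized 90-day functional outcome.

    ``favourable`` is True for mRS 0-2 and False for mRS 3-6 (the event in
    all prognostic models is the *unfavourable* outcome).
    """

    favourable: bool

    @property
    def unfavourable(self) -> bool:
        return not self.favourable


@dataclass
class PatientRecord:
    """One patient: admission covariates, biomarker, and 90-day outcomes."""

    patient_id: str
    age: float
    nihss: int
    recanalization: bool
    mr_proadm: float
    mrs_90: int
    died_90: bool
    followup_days: int
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`RowValidationError` on any field outside its range."""
        pid = self.patient_id

        def bad(field_name: str, msg: str) -> RowValidationError:
            return RowValidationError(
                f"patient {pid!r}: {field_name} {msg}", patient_id=pid, field=field_name
            )

        if not (self.age > 0):
            raise bad("age", f"must be > 0, got {self.age}")
        if not (0 <= self.nihss <= 42):
            raise bad("nihss", f"must be in 0-42, got {self.nihss}")
        if not (self.mr_proadm > 0):
            raise bad("mr_proadm", f"must be > 0, got {self.mr_proadm}")
        if not (0 <= self.mrs_90 <= 6):
            raise bad("mrs_90", f"must be in 0-6, got {self.mrs_90}")
        if (self.mrs_90 == 6) != self.died_90:
            raise bad("died_90", f"mrs_90 = 6 must coincide with died_90 "
                                 f"(mrs_90={self.mrs_90}, died_90={self.died_90})")
        if not (0 <= self.followup_days <= STUDY_HORIZON_DAYS):
            raise bad("followup_days", f"must be in 0-{STUDY_HORIZON_DAYS}, "
                                       f"got {self.followup_days}")
        if not self.died_90 and self.followup_days != STUDY_HORIZON_DAYS:
            raise bad("followup_days",
                      f"survivors are administratively censored at day "
                      f"{STUDY_HORIZON_DAYS}, got {self.followup_days}")


@dataclass
class Cohort:
    """Ordered collection of validated patient records."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes: set[str] = set()
        for r in self.records:
            (dupes if r.patient_id in seen else seen).add(r.patient_id)
        if dupes:
            raise CohortValidationError(f"duplicate patient_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def require_nonempty(self) -> None:
        if not self.records:
            raise CohortValidationError("cohort is empty; analysis requires records")

    # -- array/table views -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "age": r.age,
                "nihss": r.nihss,
                "recanalization": int(r.recanalization),
                "mr_proadm": r.mr_proadm,
                "mrs_90": r.mrs_90,
                "died_90": int(r.died_90),
                "followup_days": r.followup_days,
            }
            row.update(r.extras)
            rows.append(row)
        return pd.DataFrame(rows)

    def outcome_labels(self) -> list[OutcomeLabel]:
        return [dichotomize_outcome(r) for r in self.records]

    def unfavourable(self) -> np.ndarray:
        """0/1 vector of the unfavourable-outcome event indicator."""
        return np.array([0 if lab.favourable else 1 for lab in self.outcome_labels()])

    def covariate_matrix(self, covariates: list[str]) -> np.ndarray:
        df = self.to_dataframe()
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise CohortSchemaError(f"unknown covariates: {missing}")
        return df[covariates].to_numpy(dtype=float)


def dichotomize_outcome(record: PatientRecord) -> OutcomeLabel:
    """Map mRS at day 90 to the favourable (0-2) / unfavourable (3-6) dichotomy."""
    if not (0 <= record.mrs_90 <= 6):
        raise RowValidationError(
            f"patient {record.patient_id!r}: mrs_90 must be in 0-6, got {record.mrs_90}",
            patient_id=record.patient_id, field="mrs_90",
        )
    return OutcomeLabel(favourable=record.mrs_90 <= 2)


def _parse_bool(value, pid: str, field_name: str) -> bool:
    try:
        iv = int(float(value))
    except (TypeError, ValueError):
        raise RowValidationError(
            f"patient {pid!r}: {field_name} must be 0/1, got {value!r}",
            patient_id=pid, field=field_name,
        ) from None
    if iv not in (0, 1):
        raise RowValidationError(
            f"patient {pid!r}: {field_name} must be 0/1, got {value!r}",
            patient_id=pid, field=field_name,
        )
    return bool(iv)


def _parse_num(value, pid: str, field_name: str, kind=float):
    try:
        out = kind(float(value))
    except (TypeError, ValueError):
        raise RowValidationError(
            f"patient {pid!r}: {field_name} is not parseable: {value!r}",
            patient_id=pid, field=field_name,
        ) from None
    if kind is int and float(value) != out:
        raise RowValidationError(
            f"patient {pid!r}: {field_name} must be an integer, got {value!r}",
            patient_id=pid, field=field_name,
        )
    return out


def read_cohort(path, strict_eligibility: bool = False,
                column_aliases: dict[str, str] | None = None) -> Cohort:
    """Read and validate a cohort CSV file.

    Parameters
    ----------
    path : str or path-like
        Comma-separated UTF-8 file with a header row; booleans encoded 0/1.
    strict_eligibility : bool
        When True, rows with admission NIHSS below 4 (minor stroke under the
        study's "NIHSS more than 3" inclusion rule) are excluded; the number
        of exclusions is logged.
    column_aliases : dict, optional
        Mapping of file header name -> canonical column name, for files whose
        headers deviate from the fixed snake-case schema.

    Missing required values reject the row (complete-case analysis), except a
    survivor's blank ``followup_days``, which is forced to the 90-day
    administrative censoring horizon.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    if column_aliases:
        df = df.rename(columns={k.strip().lower(): v for k, v in column_aliases.items()})

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CohortSchemaError(f"required column missing from header: {col!r}")

    records: list[PatientRecord] = []
    n_ineligible = 0
    n_incomplete = 0
    for _, row in df.iterrows():
        pid = row["patient_id"]
        if pd.isna(pid) or str(pid).strip() == "":
            raise RowValidationError("row with missing patient_id", field="patient_id")
        pid = str(pid).strip()

        core = {c: row[c] for c in REQUIRED_COLUMNS if c != "followup_days"}
        missing = [c for c, v in core.items() if pd.isna(v) or str(v).strip() == ""]
        if missing:
            n_incomplete += 1
            logger.warning("rejecting patient %r: missing required field(s) %s", pid, missing)
            continue

        died = _parse_bool(row["died_90"], pid, "died_90")
        fup_raw = row["followup_days"]
        if pd.isna(fup_raw) or str(fup_raw).strip() == "":
            if died:
                raise RowValidationError(
                    f"patient {pid!r}: deaths must state followup_days (day of death)",
                    patient_id=pid, field="followup_days",
                )
            fup = STUDY_HORIZON_DAYS
        else:
            fup = _parse_num(fup_raw, pid, "followup_days", int)

        record = PatientRecord(
            patient_id=pid,
            age=_parse_num(row["age"], pid, "age"),
            nihss=_parse_num(row["nihss"], pid, "nihss", int),
            recanalization=_parse_bool(row["recanalization"], pid, "recanalization"),
            mr_proadm=_parse_num(row["mr_proadm"], pid, "mr_proadm"),
            mrs_90=_parse_num(row["mrs_90"], pid, "mrs_90", int),
            died_90=died,
            followup_days=fup,
            extras={c: row[c] for c in OPTIONAL_COLUMNS
                    if c in df.columns and not pd.isna(row[c])},
        )
        record.validate()

        if strict_eligibility and record.nihss < ELIGIBILITY_MIN_NIHSS:
            n_ineligible += 1
            continue
        records.append(record)

    if strict_eligibility and n_ineligible:
        logger.info("strict eligibility: excluded %d record(s) with NIHSS < %d",
                    n_ineligible, ELIGIBILITY_MIN_NIHSS)
    if n_incomplete:
        logger.info("complete-case filter: rejected %d incomplete record(s)", n_incomplete)

    return Cohort(records=records, provenance=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV with booleans encoded 0/1."""
    cohort.to_dataframe().to_csv(path, index=False)
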