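"""End-to-end analysis: cohort -> structured JSON report.

Runs the full added-prognostic-value analysis on one cohort: dichotomize the
90-day outcome, fit the clinical baseline model (age + NIHSS +
recanalization) and the biomarker-augmented model, compare their AUCs with
DeLong's test, compute the category-free NRI between their risks, run the
SPAN-100 + biomarker-quintile reclassification with its categorical NRI, and
estimate Kaplan-Meier curves with a log-rank test across biomarker
quintiles. Degenerate stages (single-class outcome, no deaths) are reported
as skipped sections with a reason rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .cohort import Cohort
from .discrimination import delong_test
from .errors import StrokemarkerError
from .reclassification import (
    build_reclassification_table,
    categorical_nri_from_table,
    category_free_nri,
    span_quintile_predictions,
)
from .risk import (
    MODEL1_COVARIATES,
    MODEL2_COVARIATES,
    assign_quintiles,
    backward_eliminate,
    fit_logistic,
)
from .survival import km_by_group, km_tidy_table, logrank_test

logger = logging.getLogger(__name__)


class AnalysisConfig(BaseModel):
    """Tunable analysis settings (see the methods documentation)."""

    binning_mode: Literal["empirical-quantile", "equal-width"] = "empirical-quantile"
    use_backward_elimination: bool = False
    p_removal: float = 0.10
    forced_covariates: list[str] = Field(default_factory=lambda: list(MODEL2_COVARIATES))
    trend_test: bool = True
    seed: Optional[int] = None

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class Section(BaseModel):
    """One report section: either computed data or an explicit skip reason."""

    status: Literal["ok", "skipped"]
    reason: Optional[str] = None
    data: Optional[dict] = None


class CohortSummary(BaseModel):
    n: int
    n_events: int
    n_nonevents: int
    n_deaths: int
    median_age: float
    median_nihss: float
    recanalization_rate: float
    biomarker_median_unfavourable: Optional[float] = None
    biomarker_median_favourable: Optional[float] = None


class Provenance(BaseModel):
    software: str
    version: str
    config_hash: str
    seed: Optional[int] = None
    cohort_provenance: str = ""


class AnalysisReport(BaseModel):
    """Full structured report; every section is present or explicitly skipped."""

    cohort_summary: CohortSummary
    model1: Section
    model2: Section
    auc_comparison: Section
    category_free_nri: Section
    reclassification: Section
    survival: Section
    provenance: Provenance

    def n_ok_sections(self) -> int:
        return sum(getattr(self, name).status == "ok"
                   for name in ("model1", "model2", "auc_comparison",
                                "category_free_nri", "reclassification", "survival"))


def _summarize(cohort: Cohort) -> CohortSummary:
    df = cohort.to_dataframe()
    unfav = cohort.unfavourable().astype(bool)
    summary = CohortSummary(
        n=len(cohort),
        n_events=int(unfav.sum()),
        n_nonevents=int((~unfav).sum()),
        n_deaths=int(df["died_90"].sum()),
        median_age=float(df["age"].median()),
        median_nihss=float(df["nihss"].median()),
        recanalization_rate=float(df["recanalization"].mean()),
    )
    if unfav.any():
        summary.biomarker_median_unfavourable = float(df.loc[unfav, "mr_proadm"].median())
    if (~unfav).any():
        summary.biomarker_median_favourable = float(df.loc[~unfav, "mr_proadm"].median())
    return summary


def _section(stage: str, fn) -> Section:
    try:
        return Section(status="ok", data=fn())
    except StrokemarkerError as exc:
        logger.warning("[%s] skipped: %s", stage, exc)
        return Section(status="skipped", reason=f"{stage}: {exc}")


def run_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Execute every analysis stage on a validated cohort."""
    config = config or AnalysisConfig()
    cohort.require_nonempty()
    df = cohort.to_dataframe()
    labels = cohort.unfavourable()

    def fit_model(covariates):
        if config.use_backward_elimination:
            return backward_eliminate(cohort, covariates,
                                      p_removal=config.p_removal,
                                      forced=set(config.forced_covariates)
                                      & set(covariates))
        return fit_logistic(cohort, covariates)

    fits: dict[str, object] = {}

    def model_section(name, covariates):
        def compute():
            fit = fit_model(covariates)
            fits[name] = fit
            return fit.to_dict()
        return _section(name, compute)

    logger.info("[models] fitting baseline and biomarker-augmented models")
    model1 = model_section("model1", list(MODEL1_COVARIATES))
    model2 = model_section("model2", list(MODEL2_COVARIATES))

    def auc_section():
        if "model1" not in fits or "model2" not in fits:
            raise StrokemarkerError("requires both fitted models")
        return delong_test(fits["model1"].fitted, fits["model2"].fitted,
                           labels).to_dict()

    def nri_section():
        if "model1" not in fits or "model2" not in fits:
            raise StrokemarkerError("requires both fitted models")
        return category_free_nri(fits["model1"].fitted, fits["model2"].fitted,
                                 labels).to_dict()

    def reclass_section():
        quintiles = assign_quintiles(df["mr_proadm"].to_numpy(), mode=config.binning_mode)
        predictions = span_quintile_predictions(cohort, quintiles)
        table = build_reclassification_table(predictions, labels)
        nri = categorical_nri_from_table(table)
        return {
            "binning_mode": quintiles.mode,
            "quintile_boundaries": [list(b) for b in quintiles.boundaries],
            "table": table.to_dict(),
            "counts": table.counts(),
            "nri": nri.to_dict(),
        }

    def survival_section():
        quintiles = assign_quintiles(df["mr_proadm"].to_numpy(), mode=config.binning_mode)
        times = df["followup_days"].to_numpy(dtype=float)
        deaths = df["died_90"].to_numpy(dtype=int)
        curves = km_by_group(times, deaths, quintiles.bins)
        groups = [(times[quintiles.bins == g], deaths[quintiles.bins == g])
                  for g in sorted(np.unique(quintiles.bins))]
        lr = logrank_test(groups, trend=config.trend_test)
        return {
            "binning_mode": quintiles.mode,
            "km_curves": km_tidy_table(curves).to_dict(orient="list"),
            "logrank": lr.to_dict(),
        }

    report = AnalysisReport(
        cohort_summary=_summarize(cohort),
        model1=model1,
        model2=model2,
        auc_comparison=_section("auc_comparison", auc_section),
        category_free_nri=_section("category_free_nri", nri_section),
        reclassification=_section("reclassification", reclass_section),
        survival=_section("survival", survival_section),
        provenance=Provenance(software="strokemarker", version=__version__,
                              config_hash=config.hash(), seed=config.seed,
                              cohort_provenance=cohort.provenance),
    )
    return report


def report_json_schema() -> dict:
    """The published JSON schema the report validates against."""
    return AnalysisReport.model_json_schema()
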