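"""Logistic prognostic models, SPAN-100 scoring, and biomarker quintiles.

The prognostic question is whether the plasma biomarker adds predictive value
over the clinical baseline (age, NIHSS, recanalization therapy) for the
unfavourable 90-day outcome. Two model specifications mirror the study:

* model 1: age + NIHSS + recanalization
* model 2: model 1 + MR-proADM

:class:`OutcomeLogit` is the model object (construct from arrays or with
:meth:`OutcomeLogit.from_cohort`); :meth:`OutcomeLogit.fit` returns a
:class:`LogisticFit` results object with coefficients, standard errors, odds
ratios with 95% Wald confidence intervals, fitted risks and a ``summary()``
table. SPAN-100 (age + NIHSS, positive when > 100) and quintile assignment of
the biomarker support the reclassification analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort import Cohort, PatientRecord
from .errors import (
    CollinearityError,
    DegenerateBinningError,
    DegenerateLabelsError,
    SeparationError,
)

MODEL1_COVARIATES = ("age", "nihss", "recanalization")
MODEL2_COVARIATES = ("age", "nihss", "recanalization", "mr_proadm")

#: Wald z for the two-sided 95% confidence convention.
_Z95 = 1.96

#: Coefficients larger than this (on the logit scale) flag separation.
_SEPARATION_COEF_BOUND = 15.0


class LogisticFit:
    """Maximum-likelihood logistic fit: estimates, uncertainty, diagnostics."""

    def __init__(self, names: list[str], coef: np.ndarray, se: np.ndarray,
                 llf: float, converged: bool, n_iter: int, fitted: np.ndarray,
                 n_events: int, n_nonevents: int):
        self.names = list(names)
        self.coef = np.asarray(coef, dtype=float)
        self.se = np.asarray(se, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.fitted = np.asarray(fitted, dtype=float)
        self.n_events = int(n_events)
        self.n_nonevents = int(n_nonevents)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names, name="coef")

    @property
    def odds_ratios(self) -> pd.Series:
        return pd.Series(np.exp(self.coef), index=self.names, name="OR")

    def conf_int_or(self) -> pd.DataFrame:
        lo = np.exp(self.coef - _Z95 * self.se)
        hi = np.exp(self.coef + _Z95 * self.se)
        return pd.DataFrame({"or_low": lo, "or_high": hi}, index=self.names)

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore"):
            return pd.Series(self.coef / self.se, index=self.names, name="z")

    @property
    def pvalues(self) -> pd.Series:
        from scipy import stats
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.names, name="p")

    def wald_pvalues_noconst(self) -> pd.Series:
        return self.pvalues.drop("const", errors="ignore")

    def summary(self) -> pd.DataFrame:
        """Per-variable table: coefficient, SE, OR with 95% CI, z, p."""
        ci = self.conf_int_or()
        return pd.DataFrame({
            "coef": self.params,
            "se": pd.Series(self.se, index=self.names),
            "OR": self.odds_ratios,
            "or_low": ci["or_low"],
            "or_high": ci["or_high"],
            "z": self.zvalues,
            "p": self.pvalues,
        })

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            "variables": self.names,
            "coefficients": [float(v) for v in self.coef],
            "standard_errors": [float(v) for v in self.se],
            "odds_ratios": [float(v) for v in s["OR"]],
            "or_ci_low": [float(v) for v in s["or_low"]],
            "or_ci_high": [float(v) for v in s["or_high"]],
            "p_values": [float(v) for v in s["p"]],
            "log_likelihood": self.llf,
            "converged": self.converged,
            "n_iterations": self.n_iter,
            "n_events": self.n_events,
            "n_nonevents": self.n_nonevents,
        }


class OutcomeLogit:
    """Logistic model for a binary outcome given named covariates.

    Parameters
    ----------
    endog : array of 0/1
        Event indicator (1 = unfavourable outcome).
    exog : 2-D array
        Covariate columns, without a constant; one is prepended.
    names : list of str
        Covariate names aligned to ``exog`` columns.
    """

    def __init__(self, endog, exog, names: list[str]):
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog are not aligned")
        if len(names) != exog.shape[1]:
            raise ValueError("names do not match exog columns")
        self.exog = np.column_stack([np.ones(len(self.endog)), exog])
        self.names = ["const", *names]

    @classmethod
    def from_cohort(cls, cohort: Cohort, covariates=MODEL2_COVARIATES) -> "OutcomeLogit":
        cohort.require_nonempty()
        return cls(cohort.unfavourable(),
                   cohort.covariate_matrix(list(covariates)),
                   list(covariates))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str,
                       covariates: list[str]) -> "OutcomeLogit":
        return cls(df[outcome].to_numpy(dtype=float),
                   df[list(covariates)].to_numpy(dtype=float),
                   list(covariates))

    def _check_design(self) -> None:
        n_events = int(self.endog.sum())
        if n_events == 0 or n_events == len(self.endog):
            raise DegenerateLabelsError("both outcome classes must be present")
        if len(self.endog) < 10:
            raise ValueError("logistic fit requires at least 10 records")
        # Collinearity: name the columns involved in the smallest singular vector.
        x = self.exog
        scale = np.linalg.norm(x, axis=0)
        u, s, vt = np.linalg.svd(x / scale, full_matrices=False)
        if s[-1] < 1e-10 * s[0]:
            involved = [self.names[j] for j in np.flatnonzero(np.abs(vt[-1]) > 1e-6)]
            raise CollinearityError(f"singular design; dependent columns: {involved}")

    def fit(self, maxiter: int = 50, tol: float = 1e-10) -> LogisticFit:
        """Fit by iteratively reweighted least squares (Fisher scoring).

        Convergence on relative log-likelihood change below ``tol`` (with the
        score checked post-hoc); standard errors from the inverse observed
        information, which for the logit link equals the expected information.
        """
        self._check_design()
        glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                # separation is re-raised as SeparationError below
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                res = glm.fit(maxiter=maxiter, tol=tol, scale=1.0)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise SeparationError(f"IRLS failed: {exc}") from exc

        coef = np.asarray(res.params, dtype=float)
        fitted = np.asarray(res.fittedvalues, dtype=float)
        # Under (quasi-)complete separation the likelihood is maximized at
        # infinity: coefficients diverge while fitted risks pin to 0/1.
        if np.max(np.abs(coef)) > _SEPARATION_COEF_BOUND and (
                not res.converged
                or np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8)):
            raise SeparationError(
                "complete or quasi-complete separation detected "
                f"(max |coef| = {np.max(np.abs(coef)):.2f})"
            )
        n_events = int(self.endog.sum())
        return LogisticFit(
            names=self.names,
            coef=coef,
            se=np.asarray(res.bse, dtype=float),
            llf=float(res.llf),
            converged=bool(res.converged),
            n_iter=int(res.fit_history["iteration"]),
            fitted=fitted,
            n_events=n_events,
            n_nonevents=len(self.endog) - n_events,
        )


def fit_logistic(cohort: Cohort, covariates=MODEL2_COVARIATES) -> LogisticFit:
    """Fit the unfavourable-outcome logistic model on a cohort."""
    return OutcomeLogit.from_cohort(cohort, covariates).fit()


def backward_eliminate(cohort: Cohort, covariates, p_removal: float = 0.10,
                       forced: set[str] | frozenset[str] = frozenset()) -> LogisticFit:
    """Backwards elimination by Wald p-value.

    Iteratively drops the non-forced covariate with the largest p-value above
    ``p_removal`` and refits, until every remaining covariate is forced or
    significant at ``p_removal``. Forcing all covariates reproduces the plain
    fit (the study's final models retain a non-significant recanalization
    term, so the default pipeline forces the full covariate set).
    """
    current = list(covariates)
    unknown_forced = set(forced) - set(current)
    if unknown_forced:
        raise ValueError(f"forced covariates not in model: {sorted(unknown_forced)}")
    while True:
        fit = fit_logistic(cohort, current)
        pvals = fit.wald_pvalues_noconst()
        candidates = pvals.drop(list(forced), errors="ignore")
        if candidates.empty or candidates.max() <= p_removal:
            return fit
        current.remove(candidates.idxmax())


@dataclass(frozen=True)
class SpanStatus:
    """SPAN-100 score (age + NIHSS); positive when strictly above 100.

    A score of exactly 100 is classified negative: the defining rule names
    only ">100 positive" and "<100 negative", and this package resolves the
    boundary to non-positive.
    """

    span: float
    positive: bool


def span_status(record_or_age, nihss: int | None = None) -> SpanStatus:
    """SPAN-100 status from a :class:`PatientRecord` or (age, nihss) pair."""
    if isinstance(record_or_age, PatientRecord):
        age, nihss = record_or_age.age, record_or_age.nihss
    else:
        age = record_or_age
        if nihss is None:
            raise TypeError("span_status(age, nihss) requires both arguments")
    span = float(age) + float(nihss)
    return SpanStatus(span=span, positive=span > 100.0)


@dataclass(frozen=True)
class QuintileAssignment:
    """Per-patient quintile bins of the biomarker.

    ``bins`` are 1-based indices; ``boundaries`` are the five (low, high)
    interval pairs; ``mode`` is ``"empirical-quantile"`` (cut points at the
    20/40/60/80th percentiles, linear interpolation between order statistics,
    intervals closed on the right at each cut) or ``"equal-width"`` (five
    equal-length intervals over [min, max], last closed).
    """

    bins: np.ndarray
    boundaries: tuple[tuple[float, float], ...]
    mode: str


def assign_quintiles(values, mode: str = "empirical-quantile") -> QuintileAssignment:
    """Assign each biomarker value to one of five ordered bins."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 5:
        raise DegenerateBinningError("need a 1-D vector of at least 5 values")
    if not np.all(v > 0):
        raise ValueError("biomarker values must be positive")

    if mode == "empirical-quantile":
        if len(np.unique(v)) < 5:
            raise DegenerateBinningError(
                "fewer than 5 distinct values; empirical quintiles are degenerate"
            )
        cuts = np.quantile(v, [0.2, 0.4, 0.6, 0.8], method="linear")
    elif mode == "equal-width":
        lo, hi = float(v.min()), float(v.max())
        cuts = lo + (hi - lo) * np.arange(1, 5) / 5.0
    else:
        raise ValueError(f"unknown binning mode: {mode!r}")

    # value <= cut_k falls in bin k (intervals closed on the right at each cut);
    # the maximum lands in bin 5 in both modes.
    bins = 1 + np.searchsorted(cuts, v, side="left")
    edges = [float(v.min()), *map(float, cuts), float(v.max())]
    boundaries = tuple((edges[i], edges[i + 1]) for i in range(5))
    return QuintileAssignment(bins=bins.astype(int), boundaries=boundaries, mode=mode)
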