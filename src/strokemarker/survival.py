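"""Kaplan-Meier survival by biomarker quintile and the k-group log-rank test.

Follow-up is administratively censored at the 90-day study horizon; deaths
carry their day of death. The product-limit estimator uses the standard tie
convention: an observation censored at a death time is still counted at risk
at that time. The log-rank test is the usual k-group chi-square on k-1
degrees of freedom built from observed-minus-expected death counts and the
hypergeometric covariance at each distinct death time; a 1-df trend variant
with ordered group scores 1..k targets the "rising risk with rising
quintile" alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGroupError


@dataclass(frozen=True)
class KmCurve:
    """Product-limit estimate at each distinct death time."""

    times: np.ndarray        # ordered distinct death times
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    variance: np.ndarray     # Greenwood variance of S(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "at_risk": self.at_risk, "deaths": self.deaths,
            "survival": self.survival, "variance": self.variance,
        })

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier estimator with Greenwood variance.

    ``times`` are follow-up days; ``events`` mark deaths (1) versus
    administrative censoring (0).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(times) == 0:
        raise DegenerateGroupError("empty survival input")
    if len(times) != len(events):
        raise ValueError("times and events are not aligned")

    death_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in death_times])
    deaths = np.array([((times == t) & (events == 1)).sum() for t in death_times])
    frac = 1.0 - deaths / at_risk
    survival = np.cumprod(frac)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = deaths / (at_risk * (at_risk - deaths))
    terms = np.where(at_risk == deaths, np.nan, terms)
    variance = survival**2 * np.nancumsum(terms)
    return KmCurve(times=death_times, at_risk=at_risk, deaths=deaths,
                   survival=survival, variance=variance)


@dataclass(frozen=True)
class LogRankResult:
    """k-group log-rank test, with optional ordered-trend variant."""

    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float
    trend_statistic: float | None = None
    trend_p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "observed": [int(v) for v in self.observed],
            "expected": [float(v) for v in self.expected],
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "trend_statistic": self.trend_statistic,
            "trend_p_value": self.trend_p_value,
        }


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]],
                 trend: bool = False) -> LogRankResult:
    """Log-rank test across k groups of (follow-up days, death indicators).

    With ``trend`` the 1-df statistic ``(c'(O-E))^2 / (c'Vc)`` with scores
    ``c = 1..k`` is also computed, which is sensitive to a monotone ordering
    of the hazards across groups.
    """
    k = len(groups)
    if k < 2:
        raise DegenerateGroupError("log-rank requires at least 2 groups")
    times_list, events_list = [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e).astype(int)
        if len(t) == 0:
            raise DegenerateGroupError(f"group {gi + 1} is empty")
        times_list.append(t)
        events_list.append(e)
    group_idx = np.concatenate([np.full(len(t), gi) for gi, t in enumerate(times_list)])
    times = np.concatenate(times_list)
    events = np.concatenate(events_list)
    if events.sum() == 0:
        raise DegenerateGroupError("no deaths in any group")

    death_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in death_times:
        at_risk_mask = times >= t
        n = at_risk_mask.sum()
        n_g = np.array([(at_risk_mask & (group_idx == g)).sum() for g in range(k)])
        dying = (times == t) & (events == 1)
        d = dying.sum()
        d_g = np.array([(dying & (group_idx == g)).sum() for g in range(k)])
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            hyper = d * (n - d) / (n - 1)
            cov += hyper * (np.diag(n_g) * n - np.outer(n_g, n_g)) / n**2

    oe = observed - expected
    # chi-square on the first k-1 components (the k-th is linearly dependent)
    v_sub = cov[:k - 1, :k - 1]
    oe_sub = oe[:k - 1]
    statistic = float(oe_sub @ np.linalg.pinv(v_sub) @ oe_sub)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))

    trend_stat = trend_p = None
    if trend:
        scores = np.arange(1, k + 1, dtype=float)
        denom = float(scores @ cov @ scores)
        if denom <= 0:
            raise DegenerateGroupError("trend variance is zero")
        trend_stat = float((scores @ oe) ** 2 / denom)
        trend_p = float(stats.chi2.sf(trend_stat, 1))

    return LogRankResult(observed=observed.astype(int), expected=expected,
                         statistic=statistic, df=df, p_value=p,
                         trend_statistic=trend_stat, trend_p_value=trend_p)


def km_by_group(times, events, group_bins) -> dict[int, KmCurve]:
    """KM curve per group (e.g. biomarker quintile), keyed by group label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group_bins = np.asarray(group_bins)
    return {int(g): km_estimate(times[group_bins == g], events[group_bins == g])
            for g in np.unique(group_bins)}


def km_tidy_table(curves: dict[int, KmCurve]) -> pd.DataFrame:
    """Tidy (group, time, at-risk, deaths, survival, variance) export table."""
    frames = []
    for g, curve in sorted(curves.items()):
        f = curve.to_frame()
        f.insert(0, "group", g)
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["group", "time", "at_risk", "deaths",
                                     "survival", "variance"])
    return pd.concat(frames, ignore_index=True)
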