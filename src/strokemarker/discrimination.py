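"""ROC curves, AUC via placement values, and DeLong's test for paired AUCs.

The AUC is computed by the midrank (Mann-Whitney) formula, with ties counted
half. For each event the *placement value* is the proportion of non-events
scored strictly below it plus half the ties; symmetrically for non-events.
The mean event placement value equals the AUC, and the empirical covariance
of paired placement values across two score vectors on the same subjects
yields DeLong's variance estimator for the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateComparisonError, DegenerateLabelsError

#: Variances below this are treated as numerically zero in delong_test.
_VAR_FLOOR = 1e-15


@dataclass(frozen=True)
class RocResult:
    """ROC curve, AUC, and the DeLong structural components."""

    scores: np.ndarray
    labels: np.ndarray            # 1 = event, 0 = non-event
    auc: float
    event_placements: np.ndarray      # V10, one per event; mean = AUC
    nonevent_placements: np.ndarray   # V01, one per non-event; mean = AUC
    fpr: np.ndarray
    tpr: np.ndarray


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    ev = labels == 1
    if not ev.any() or ev.all():
        raise DegenerateLabelsError("both events and non-events are required")
    return labels, ev


def _placements(scores: np.ndarray, ev: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values (V10 per event, V01 per non-event) and AUC."""
    x, y = scores[ev], scores[~ev]          # events, non-events
    m, n = len(x), len(y)
    ranks_all = stats.rankdata(np.concatenate([x, y]), method="average")
    v10 = (ranks_all[:m] - stats.rankdata(x, method="average")) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(y, method="average")) / m
    auc = float(v10.mean())
    return v10, v01, auc


def roc_auc(scores, labels) -> RocResult:
    """ROC points at every distinct threshold plus the midrank AUC."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    labels, ev = _check_labels(np.asarray(labels))
    if len(scores) != len(labels):
        raise ValueError("scores and labels are not aligned")

    v10, v01, auc = _placements(scores, ev)

    # ROC points: sweep thresholds downward through the distinct scores.
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_ev = ev[order]
    distinct = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    tp = np.cumsum(sorted_ev)[distinct]
    fp = np.cumsum(~sorted_ev)[distinct]
    tpr = np.concatenate([[0.0], tp / ev.sum()])
    fpr = np.concatenate([[0.0], fp / (~ev).sum()])

    return RocResult(scores=scores, labels=labels, auc=auc,
                     event_placements=v10, nonevent_placements=v01,
                     fpr=fpr, tpr=tpr)


@dataclass(frozen=True)
class AucComparison:
    """DeLong comparison of two AUCs computed on the same subjects."""

    auc1: float
    auc2: float
    difference: float
    variance: float
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return {"auc_model1": self.auc1, "auc_model2": self.auc2,
                "difference": self.difference, "variance": self.variance,
                "z": self.z, "p_value": self.p_value}


def delong_test(scores1, scores2, labels) -> AucComparison:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    The variance of ``auc2 - auc1`` combines the empirical covariance
    matrices of the paired event placements (S10 / m) and non-event
    placements (S01 / n). Raises :class:`DegenerateComparisonError` when that
    variance is numerically zero (e.g. identical or rank-identical scores),
    rather than returning a 0/0 z-statistic.
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    labels, ev = _check_labels(np.asarray(labels))
    if not (len(scores1) == len(scores2) == len(labels)):
        raise ValueError("score vectors and labels are not aligned")

    v10_1, v01_1, auc1 = _placements(scores1, ev)
    v10_2, v01_2, auc2 = _placements(scores2, ev)
    m, n = int(ev.sum()), int((~ev).sum())
    if m < 2 or n < 2:
        raise DegenerateLabelsError("need at least 2 events and 2 non-events")

    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    contrast = np.array([-1.0, 1.0])
    variance = float(contrast @ (s10 / m + s01 / n) @ contrast)

    diff = auc2 - auc1
    if variance < _VAR_FLOOR:
        raise DegenerateComparisonError(
            f"variance of the AUC difference is numerically zero ({variance:.3g}); "
            "the two score vectors are rank-identical"
        )
    z = diff / np.sqrt(variance)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc1=auc1, auc2=auc2, difference=diff,
                         variance=variance, z=float(z), p_value=p)
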