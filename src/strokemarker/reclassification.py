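"""Net reclassification improvement: category-free and categorical variants.

The category-free NRI compares predicted risks from two nested models: a
subject moves "up" when the updated model raises their risk and "down" when
it lowers it. The categorical variant compares two classification rules —
here the SPAN-100 score alone versus SPAN-100 revised by biomarker quintile:
SPAN-100 negative patients in the upper three quintiles are reclassified to
the unfavourable prediction, SPAN-100 positive patients in the lower two
quintiles to the favourable prediction.

Both variants share the same summary: within events, the net proportion
moved up; within non-events, the net proportion moved down; their sum is the
overall NRI. The z-statistic uses the simple asymptotic variance
``(up + down) / n**2`` per class, summed across classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort
from .errors import DegenerateLabelsError, DegenerateTableError
from .risk import QuintileAssignment, span_status

#: Risk differences within this tolerance count as ties (no reclassification).
TIE_TOLERANCE = 1e-12

#: Quintile bins that move a SPAN-100 negative prediction up ...
UPWARD_BINS = (3, 4, 5)
#: ... and bins that move a SPAN-100 positive prediction down.
DOWNWARD_BINS = (1, 2)


@dataclass(frozen=True)
class NriResult:
    """Event/non-event components, overall NRI and asymptotic z-test."""

    event_component: float
    nonevent_component: float
    overall: float
    z: float
    p_value: float
    event_z: float
    event_p: float
    nonevent_z: float
    nonevent_p: float
    n_events: int
    n_nonevents: int

    def to_dict(self) -> dict:
        return {
            "event_component": self.event_component,
            "nonevent_component": self.nonevent_component,
            "overall": self.overall,
            "z": self.z,
            "p_value": self.p_value,
            "event_z": self.event_z,
            "event_p": self.event_p,
            "nonevent_z": self.nonevent_z,
            "nonevent_p": self.nonevent_p,
            "n_events": self.n_events,
            "n_nonevents": self.n_nonevents,
        }


def _nri_from_counts(up_e: int, down_e: int, n_e: int,
                     up_ne: int, down_ne: int, n_ne: int) -> NriResult:
    if n_e <= 0 or n_ne <= 0:
        raise DegenerateTableError("both events and non-events are required")
    ev = (up_e - down_e) / n_e
    ne = (down_ne - up_ne) / n_ne
    overall = ev + ne
    var = (up_e + down_e) / n_e**2 + (up_ne + down_ne) / n_ne**2

    def ztest(value: float, variance: float) -> tuple[float, float]:
        if variance <= 0:
            return (0.0, 1.0) if value == 0 else (np.inf * np.sign(value), 0.0)
        z = value / np.sqrt(variance)
        return float(z), float(2.0 * stats.norm.sf(abs(z)))

    z, p = ztest(overall, var)
    ez, ep = ztest(ev, (up_e + down_e) / n_e**2)
    nz, np_ = ztest(ne, (up_ne + down_ne) / n_ne**2)
    return NriResult(event_component=ev, nonevent_component=ne, overall=overall,
                     z=z, p_value=p, event_z=ez, event_p=ep,
                     nonevent_z=nz, nonevent_p=np_,
                     n_events=n_e, n_nonevents=n_ne)


def category_free_nri(risks_old, risks_new, labels,
                      tie_tolerance: float = TIE_TOLERANCE) -> NriResult:
    """Category-free (continuous) NRI between two risk vectors.

    Any increase in predicted risk beyond ``tie_tolerance`` counts as an
    upward move and any decrease as a downward move, independent of risk
    categories and of model calibration (the statistic depends on risks only
    through the sign of their change).
    """
    risks_old = np.asarray(risks_old, dtype=float)
    risks_new = np.asarray(risks_new, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(risks_old) == len(risks_new) == len(labels)):
        raise ValueError("risk vectors and labels are not aligned")
    ev = labels == 1
    if not ev.any() or ev.all():
        raise DegenerateLabelsError("both events and non-events are required")

    delta = risks_new - risks_old
    up = delta > tie_tolerance
    down = delta < -tie_tolerance
    return _nri_from_counts(
        up_e=int(up[ev].sum()), down_e=int(down[ev].sum()), n_e=int(ev.sum()),
        up_ne=int(up[~ev].sum()), down_ne=int(down[~ev].sum()), n_ne=int((~ev).sum()),
    )


@dataclass(frozen=True)
class ClassPair:
    """Predicted class (True = unfavourable) under the baseline and updated rule."""

    baseline_unfavourable: bool
    updated_unfavourable: bool


def span_quintile_predictions(cohort: Cohort,
                              quintiles: QuintileAssignment) -> list[ClassPair]:
    """Baseline SPAN-100 prediction and its biomarker-quintile revision.

    Baseline predicts unfavourable iff SPAN-100 positive. The revision flips
    SPAN-100 negative patients in quintiles 3-5 to unfavourable and SPAN-100
    positive patients in quintiles 1-2 to favourable; all others keep their
    baseline prediction.
    """
    cohort.require_nonempty()
    if len(quintiles.bins) != len(cohort):
        raise ValueError("quintiles are not aligned to the cohort")
    pairs = []
    for record, bin_ in zip(cohort, quintiles.bins):
        positive = span_status(record).positive
        baseline = positive
        if not positive and bin_ in UPWARD_BINS:
            updated = True
        elif positive and bin_ in DOWNWARD_BINS:
            updated = False
        else:
            updated = baseline
        pairs.append(ClassPair(baseline_unfavourable=baseline,
                               updated_unfavourable=updated))
    return pairs


@dataclass(frozen=True)
class ReclassificationTable:
    """Baseline-by-updated class counts, within events and within non-events.

    Each 2x2 block is indexed [baseline][updated] with 0 = favourable
    prediction, 1 = unfavourable prediction.
    """

    events: np.ndarray
    nonevents: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.nonevents.sum())

    def counts(self) -> dict:
        return {
            "events_up": int(self.events[0, 1]),
            "events_down": int(self.events[1, 0]),
            "n_events": self.n_events,
            "nonevents_up": int(self.nonevents[0, 1]),
            "nonevents_down": int(self.nonevents[1, 0]),
            "n_nonevents": self.n_nonevents,
        }

    def to_dict(self) -> dict:
        return {"events": self.events.astype(int).tolist(),
                "nonevents": self.nonevents.astype(int).tolist()}

    @classmethod
    def from_counts(cls, events_up: int, events_down: int, n_events: int,
                    nonevents_up: int, nonevents_down: int,
                    n_nonevents: int) -> "ReclassificationTable":
        """Build a table from published up/down/total counts.

        Unchanged patients are placed on the diagonal; the split of the
        diagonal between classes does not affect any NRI quantity, so the
        favourable-favourable cell absorbs it.
        """
        for label, (moved, total) in {
            "events": (events_up + events_down, n_events),
            "nonevents": (nonevents_up + nonevents_down, n_nonevents),
        }.items():
            if moved > total:
                raise ValueError(f"{label}: moved counts exceed the total")
        ev = np.array([[n_events - events_up - events_down, events_up],
                       [events_down, 0]])
        ne = np.array([[n_nonevents - nonevents_up - nonevents_down, nonevents_up],
                       [nonevents_down, 0]])
        return cls(events=ev, nonevents=ne)


def build_reclassification_table(predictions: list[ClassPair],
                                 labels) -> ReclassificationTable:
    """Cross-tabulate baseline vs updated class within events and non-events."""
    labels = np.asarray(labels).astype(int)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels are not aligned")
    ev = np.zeros((2, 2), dtype=int)
    ne = np.zeros((2, 2), dtype=int)
    for pair, lab in zip(predictions, labels):
        block = ev if lab == 1 else ne
        block[int(pair.baseline_unfavourable), int(pair.updated_unfavourable)] += 1
    return ReclassificationTable(events=ev, nonevents=ne)


def categorical_nri_from_table(table: ReclassificationTable) -> NriResult:
    """Categorical NRI from a reclassification table.

    Within events an upward move (favourable -> unfavourable prediction) is
    correct; within non-events a downward move is correct.
    """
    c = table.counts()
    return _nri_from_counts(
        up_e=c["events_up"], down_e=c["events_down"], n_e=c["n_events"],
        up_ne=c["nonevents_up"], down_ne=c["nonevents_down"], n_ne=c["n_nonevents"],
    )
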