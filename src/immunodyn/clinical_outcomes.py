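"""RECIST-derived endpoint statistics with protocol censoring rules.

Response assessments enter as categorical RECIST calls (CR/PR/SD/PD/NE) on a
study-week timeline.  Tumor assessments are scheduled every 6 weeks (±1) for
the first 24 weeks of treatment and every 8 weeks (±1) thereafter.  PFS runs
from treatment start to the first progression or death, except that an event
occurring after two or more missed scheduled visits is censored back at the
last evaluable assessment before the gap.  Survival curves are Kaplan–Meier
product-limit estimates with Greenwood log(−log) pointwise intervals and a
Brookmeyer–Crowley-style median CI, reported at the 80% level by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .errors import ValidationError

CR, PR, SD, PD, NE = "CR", "PR", "SD", "PD", "NE"
CATEGORIES = frozenset({CR, PR, SD, PD, NE})

PRIMARY = "primary"
ACQUIRED = "acquired"

#: weeks on prior checkpoint blockade separating primary from acquired resistance
RESISTANCE_CUTOFF_WEEKS = 24.0
#: mutations per megabase separating TMB-low from TMB-high
TMB_CUTOFF = 10.0
#: percent tumor cells staining separating PD-L1-negative from positive
PDL1_CUTOFF = 1.0


@dataclass(frozen=True)
class Assessment:
    study_week: float
    category: str
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown RECIST category {self.category!r}")


@dataclass
class PatientRecord:
    patient_id: str
    module: str = ""
    cohort: str = ""
    prior_icb_progression_week: float | None = None
    assessments: list[Assessment] = field(default_factory=list)
    death_week: float | None = None
    last_alive_week: float = 0.0
    pd_l1_tc_percent: float | None = None
    tmb_mut_per_mb: float | None = None
    histology: str = ""
    metastasis_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        weeks = [a.study_week for a in self.assessments]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValidationError(
                f"{self.patient_id}: assessment weeks must be strictly increasing"
            )
        if self.death_week is not None and weeks and self.death_week < weeks[-1]:
            raise ValidationError(
                f"{self.patient_id}: death precedes the last assessment"
            )


@dataclass(frozen=True)
class AssessmentSchedule:
    """Scheduled tumor-assessment grid with a detection window."""

    first_interval: float = 6.0
    switch_week: float = 24.0
    later_interval: float = 8.0
    window: float = 1.0

    def visit_weeks(self, through_week: float) -> list[float]:
        weeks: list[float] = []
        w = self.first_interval
        while w <= min(self.switch_week, through_week):
            weeks.append(w)
            w += self.first_interval
        w = self.switch_week + self.later_interval
        while w <= through_week:
            weeks.append(w)
            w += self.later_interval
        return weeks


DEFAULT_SCHEDULE = AssessmentSchedule()


def classify_resistance(progression_week: float) -> str:
    """Primary (progression within ≤24 weeks of prior ICB) vs acquired (>24)."""
    if progression_week <= 0:
        raise ValidationError("progression week must be positive")
    return PRIMARY if progression_week <= RESISTANCE_CUTOFF_WEEKS else ACQUIRED


def classify_tmb(mut_per_mb: float) -> str:
    """TMB-high (≥10 mut/Mb) vs TMB-low (<10)."""
    if mut_per_mb < 0:
        raise ValidationError("TMB must be non-negative")
    return "high" if mut_per_mb >= TMB_CUTOFF else "low"


def classify_pdl1(tc_percent: float) -> str:
    """PD-L1-positive (≥1% tumor cells) vs negative (<1%)."""
    if not 0 <= tc_percent <= 100:
        raise ValidationError("PD-L1 TC percent must be in [0, 100]")
    return "positive" if tc_percent >= PDL1_CUTOFF else "negative"


def best_overall_response(record: PatientRecord, sd_min_week: float = 6.0) -> str:
    """Best overall RECIST response; CR/PR require confirmation.

    Stable disease counts only when a non-PD evaluable assessment is seen at
    or after ``sd_min_week`` (default: the first scheduled assessment) and
    before any progression.
    """
    confirmed = {a.category for a in record.assessments
                 if a.confirmed and a.category in (CR, PR)}
    if CR in confirmed:
        return CR
    if PR in confirmed:
        return PR
    pd_week = next((a.study_week for a in record.assessments if a.category == PD),
                   None)
    for a in record.assessments:
        if a.category in (SD, PR, CR) and a.study_week >= sd_min_week:
            if pd_week is None or a.study_week < pd_week:
                return SD
    if pd_week is not None:
        return PD
    return NE


@dataclass(frozen=True)
class RateResult:
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Proportion as a percentage, reported to 0.1%."""
        return round(100.0 * self.proportion, 1)


def compute_orr(records: Iterable[PatientRecord]) -> RateResult:
    """Objective response rate: confirmed CR/PR over all treated patients."""
    records = list(records)
    if not records:
        raise ValidationError("empty cohort")
    n_resp = sum(best_overall_response(r) in (CR, PR) for r in records)
    return RateResult(numerator=n_resp, denominator=len(records))


def compute_dcr(
    records: Iterable[PatientRecord],
    landmark_week: float,
    schedule: AssessmentSchedule = DEFAULT_SCHEDULE,
) -> RateResult:
    """Disease control rate at a landmark week (12 or 24).

    A patient counts when disease control (CR/PR/SD) is maintained through
    the landmark: an evaluable non-PD assessment at or beyond the landmark
    (within the schedule's window) and no progression or death on or before
    it.
    """
    if landmark_week not in (12, 24):
        raise ValidationError("landmark must be 12 or 24 weeks")
    records = list(records)
    if not records:
        raise ValidationError("empty cohort")
    n = 0
    for r in records:
        pd_week = next(
            (a.study_week for a in r.assessments if a.category == PD), None
        )
        if pd_week is not None and pd_week <= landmark_week:
            continue
        if r.death_week is not None and r.death_week <= landmark_week:
            continue
        controlled = any(
            a.category in (CR, PR, SD)
            and a.study_week >= landmark_week - schedule.window
            for a in r.assessments
        )
        if controlled:
            n += 1
    return RateResult(numerator=n, denominator=len(records))


def derive_pfs(
    record: PatientRecord,
    schedule: AssessmentSchedule = DEFAULT_SCHEDULE,
) -> tuple[float, bool]:
    """(time in weeks, event flag) for progression-free survival.

    Event at the first progression or death; if the event follows two or
    more missed scheduled visits (no evaluable assessment in a visit's ±
    window), the patient is instead censored at the last evaluable
    assessment before the gap.  Patients without progression or death are
    censored at their last evaluable assessment.
    """
    evaluable_weeks = [a.study_week for a in record.assessments if a.category != NE]
    non_pd_weeks = [
        a.study_week for a in record.assessments if a.category in (CR, PR, SD)
    ]
    pd_week = next((a.study_week for a in record.assessments if a.category == PD),
                   None)
    event_candidates = [w for w in (pd_week, record.death_week) if w is not None]

    if not event_candidates:
        if not evaluable_weeks:
            warnings.warn(
                f"{record.patient_id}: no assessments and no death; censored at 0",
                stacklevel=2,
            )
            return 0.0, False
        return max(non_pd_weeks, default=0.0), False

    event_time = min(event_candidates)
    last_eval = max((w for w in evaluable_weeks if w < event_time), default=0.0)
    missed = [
        w
        for w in schedule.visit_weeks(event_time)
        if last_eval < w < event_time
        and not any(abs(w - e) <= schedule.window for e in evaluable_weeks)
    ]
    if len(missed) >= 2:
        return last_eval, False
    return event_time, True


def derive_os(record: PatientRecord) -> tuple[float, bool]:
    """(time in weeks, event flag) for overall survival."""
    if record.death_week is not None:
        return record.death_week, True
    return record.last_alive_week, False


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # NaN when S never reaches 0.5
    median_ci: tuple[float, float]  # bounds may be infinite
    ci_level: float = 0.80

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(
    durations: Sequence[float],
    events: Sequence[bool],
    ci_level: float = 0.80,
) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with median and its CI.

    The median is the smallest observed event time with S(t) ≤ 0.5 (step
    convention); the CI comes from the times at which the Greenwood
    log(−log) confidence band crosses 0.5 (Brookmeyer–Crowley construction).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValidationError("at least one subject required")
    if (durations < 0).any():
        raise ValidationError("negative survival times")

    kmf = KaplanMeierFitter(alpha=1.0 - ci_level)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(durations, event_observed=events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    event_table = kmf.event_table
    return SurvivalCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=event_table["at_risk"].to_numpy(dtype=float),
        median=median if np.isfinite(median) else float("nan"),
        median_ci=(lo, hi),
        ci_level=ci_level,
    )


def cohort_km(
    records: Iterable[PatientRecord],
    endpoint: str = "pfs",
    ci_level: float = 0.80,
    schedule: AssessmentSchedule = DEFAULT_SCHEDULE,
) -> SurvivalCurve:
    """Kaplan–Meier curve of PFS or OS for a cohort of patient records."""
    records = list(records)
    if endpoint == "pfs":
        pairs = [derive_pfs(r, schedule) for r in records]
    elif endpoint == "os":
        pairs = [derive_os(r) for r in records]
    else:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    times = [t for t, _ in pairs]
    flags = [e for _, e in pairs]
    return km_estimate(times, flags, ci_level=ci_level)
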