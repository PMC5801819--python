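"""Domain types for ALS cohorts and deterministic preprocessing.

The unit of analysis is a subject followed longitudinally on the ALSFRS, a
physician-reported functional score bounded in [0, 40] (40 = normal function,
typically non-increasing).  Each subject carries a self-reported disease-onset
time, expressed in days from trial start (negative: onset precedes the trial).

The *onset anchor* is an artificial observation -- the maximum score of 40
placed at the subject's onset time -- appended to the visit list and treated
as observed data downstream.  It acts as a leverage point that stabilises the
per-subject slope when few real visits are available.

All operations here are pure: they never mutate their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

SCORE_MIN = 0.0
SCORE_MAX = 40.0

#: Days per month used when a window is given in months ("3 months" -> 91 days
#: by default; the exact cutoff is a parameter everywhere it matters).
DAYS_PER_MONTH = 30.44


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant."""


@dataclass(frozen=True)
class VisitObservation:
    """A single (time, score) measurement.

    ``is_anchor`` flags the artificial onset-anchor point (score 40 at the
    subject's onset time); anchors are modelling devices, never outcomes.
    """

    time_days: float
    score: float
    is_anchor: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_days):
            raise ValidationError(f"visit time must be finite, got {self.time_days}")
        if not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise ValidationError(
                f"score {self.score} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
            )
        if self.is_anchor and self.score != SCORE_MAX:
            raise ValidationError("anchor visits must carry the maximum score of 40")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifier, onset time, ordered visits, covariates.

    ``onset_time_days`` is self-reported disease onset relative to trial
    start (<= 0); ``None`` means not reported.  Covariate values may be NaN
    (missing); complete-case subsetting handles those downstream.
    """

    subject_id: str
    onset_time_days: float | None
    visits: tuple[VisitObservation, ...]
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [v.time_days for v in self.visits]
        if any(b < a for a, b in zip(times, times[1:])):
            object.__setattr__(
                self, "visits", tuple(sorted(self.visits, key=lambda v: v.time_days))
            )
        if sum(v.is_anchor for v in self.visits) > 1:
            raise ValidationError(f"subject {self.subject_id}: more than one anchor visit")
        if self.onset_time_days is not None:
            if not math.isfinite(self.onset_time_days):
                raise ValidationError(f"subject {self.subject_id}: non-finite onset time")
            if self.onset_time_days > 0:
                raise ValidationError(
                    f"subject {self.subject_id}: onset time {self.onset_time_days} is "
                    "after trial start (must be <= 0)"
                )
            obs = [v.time_days for v in self.visits if not v.is_anchor]
            if obs and self.onset_time_days > min(obs):
                raise ValidationError(
                    f"subject {self.subject_id}: onset time {self.onset_time_days} "
                    f"follows the first observed visit at {min(obs)}"
                )

    @property
    def has_anchor(self) -> bool:
        return any(v.is_anchor for v in self.visits)

    @property
    def observed_visits(self) -> tuple[VisitObservation, ...]:
        """Real (non-anchor) visits only."""
        return tuple(v for v in self.visits if not v.is_anchor)


@dataclass(frozen=True)
class Cohort:
    """A list of subjects plus the covariate names they may carry."""

    subjects: tuple[SubjectRecord, ...]
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass(frozen=True)
class CollapsedCovariate:
    """OLS collapse of a longitudinal covariate: intercept at t=0 and slope per day.

    ``slope`` is NaN when the series has a single point (or no time spread),
    in which case only the intercept (= that value) is defined.
    """

    intercept: float
    slope: float
    n_points: int


# --- ALSFRS-R -> ALSFRS conversion -----------------------------------------

ALSFRSR_ITEMS = (
    "q1_speech",
    "q2_salivation",
    "q3_swallowing",
    "q4_handwriting",
    "q5_cutting",
    "q6_dressing_hygiene",
    "q7_turning_in_bed",
    "q8_walking",
    "q9_climbing_stairs",
    "r1_dyspnea",
)


def convert_alsfrsr_to_alsfrs(subscores) -> int:
    """Convert ten ALSFRS-R sub-scores to the 0-40 ALSFRS.

    The revised scale's first nine items (motor and bulbar function) are summed
    together with the first respiratory item, R1: Dyspnea.  Input order is
    Q1..Q9 then R1-Dyspnea (see :data:`ALSFRSR_ITEMS`).
    """
    subscores = list(subscores)
    if len(subscores) != len(ALSFRSR_ITEMS):
        raise ValidationError(
            f"expected {len(ALSFRSR_ITEMS)} sub-scores, got {len(subscores)}"
        )
    total = 0
    for name, value in zip(ALSFRSR_ITEMS, subscores):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValidationError(f"missing sub-score for item {name}")
        if value not in (0, 1, 2, 3, 4):
            raise ValidationError(f"item {name}: sub-score {value} not in 0..4")
        total += int(value)
    return total


# --- windowing and endpoints ------------------------------------------------

def truncate_window(subject: SubjectRecord, cutoff_days: float) -> SubjectRecord:
    """Keep anchor visits plus all real visits at or before ``cutoff_days``.

    ``cutoff_days = 0`` keeps only the baseline visit (plus any anchor), the
    harshest data-capture window under which the onset-anchored model still
    operates.
    """
    if cutoff_days < 0:
        raise ValidationError(f"cutoff_days must be >= 0, got {cutoff_days}")
    kept = tuple(
        v for v in subject.visits if v.is_anchor or v.time_days <= cutoff_days
    )
    if not any(not v.is_anchor for v in kept):
        raise ValidationError(
            f"subject {subject.subject_id}: no visits at or before day "
            f"{cutoff_days:g}; unusable for fitting"
        )
    return replace(subject, visits=kept)


def first_score_after(
    subject: SubjectRecord, day: float = 365.0
) -> tuple[float, float] | None:
    """Earliest real visit at or after ``day`` as ``(time_days, score)``.

    This defines the prediction endpoint: with ``day=365`` it is the subject's
    first ALSFRS score at, or after, one year from trial start (FRS365).
    Returns ``None`` when the subject has no qualifying visit.  Anchor visits
    never qualify.
    """
    for v in subject.visits:
        if not v.is_anchor and v.time_days >= day:
            return (v.time_days, v.score)
    return None


def add_onset_anchor(subject: SubjectRecord) -> SubjectRecord:
    """Append the artificial onset-anchor observation to a subject.

    The anchor assumes the subject scored the maximum of 40 at their
    self-reported disease-onset time, and is treated as an observed value by
    the anchored models.  Subjects without a reported onset time cannot be
    anchored and must be dropped by the caller.
    """
    if subject.onset_time_days is None:
        raise ValidationError(
            f"subject {subject.subject_id}: no self-reported onset time; "
            "cannot add onset anchor"
        )
    if subject.has_anchor:
        raise ValidationError(f"subject {subject.subject_id}: already anchored")
    anchor = VisitObservation(
        time_days=subject.onset_time_days, score=SCORE_MAX, is_anchor=True
    )
    visits = tuple(sorted(subject.visits + (anchor,), key=lambda v: v.time_days))
    return replace(subject, visits=visits)


def anchor_cohort(cohort: Cohort, drop_missing_onset: bool = False) -> Cohort:
    """Anchor every subject in a cohort.

    With ``drop_missing_onset`` subjects lacking an onset time are removed
    (mirroring study-population cleaning); otherwise they raise.
    """
    kept = []
    for s in cohort.subjects:
        if s.onset_time_days is None and drop_missing_onset:
            continue
        kept.append(s if s.has_anchor else add_onset_anchor(s))
    return Cohort(subjects=tuple(kept), covariate_names=cohort.covariate_names)


# --- covariate machinery ----------------------------------------------------

def collapse_covariate(series, cutoff_days: float) -> CollapsedCovariate:
    """OLS slope/intercept of a longitudinal covariate over a time window.

    ``series`` is an iterable of ``(time_days, value)``.  Points after
    ``cutoff_days`` are discarded; the remaining points are collapsed by
    ordinary least squares of value on time.  A single surviving point yields
    its value as intercept and a missing (NaN) slope.
    """
    pts = [(t, x) for t, x in series if t <= cutoff_days]
    if not pts:
        raise ValidationError("covariate series empty after truncation")
    t = np.asarray([p[0] for p in pts], dtype=float)
    x = np.asarray([p[1] for p in pts], dtype=float)
    if len(pts) == 1 or np.ptp(t) == 0.0:
        return CollapsedCovariate(intercept=float(x.mean()), slope=float("nan"),
                                  n_points=len(pts))
    slope, intercept = np.polyfit(t, x, 1)
    return CollapsedCovariate(intercept=float(intercept), slope=float(slope),
                              n_points=len(pts))


def normalize_covariates(
    cohort: Cohort, names
) -> tuple[Cohort, dict[str, tuple[float, float]]]:
    """Z-score the named covariates using the cohort's own sample statistics.

    Returns the transformed cohort and a ``{name: (mean, sd)}`` table so the
    identical transform can be reapplied to held-out subjects (training-set
    statistics, never recomputed on validation data).  Missing (NaN) entries
    are ignored when computing statistics and stay missing afterwards.
    """
    table: dict[str, tuple[float, float]] = {}
    for name in names:
        vals = np.asarray(
            [s.covariates.get(name, float("nan")) for s in cohort.subjects], dtype=float
        )
        ok = vals[~np.isnan(vals)]
        if len(ok) < 2:
            raise ValidationError(f"covariate {name!r}: fewer than 2 non-missing values")
        mean, sd = float(ok.mean()), float(ok.std(ddof=1))
        if sd == 0.0:
            raise ValidationError(f"covariate {name!r} has zero variance")
        table[name] = (mean, sd)
    return apply_normalization(cohort, table), table


def apply_normalization(
    cohort: Cohort, table: dict[str, tuple[float, float]]
) -> Cohort:
    """Apply a previously computed mean/SD table to a cohort."""
    subjects = []
    for s in cohort.subjects:
        cov = dict(s.covariates)
        for name, (mean, sd) in table.items():
            if name in cov and not math.isnan(cov[name]):
                cov[name] = (cov[name] - mean) / sd
        subjects.append(replace(s, covariates=cov))
    return Cohort(subjects=tuple(subjects), covariate_names=cohort.covariate_names)


def complete_case_subset(cohort: Cohort, covariate: str) -> Cohort:
    """Drop subjects with a missing value for ``covariate``."""
    if covariate not in cohort.covariate_names:
        raise ValidationError(f"unknown covariate {covariate!r}")
    kept = tuple(
        s
        for s in cohort.subjects
        if covariate in s.covariates and not math.isnan(s.covariates[covariate])
    )
    if not kept:
        raise ValidationError(f"no complete cases for covariate {covariate!r}")
    return Cohort(subjects=kept, covariate_names=cohort.covariate_names)
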