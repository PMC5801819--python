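"""Synthetic placebo-cohort generator.

Emulates the structure of a pooled ALS clinical-trials placebo population:
roughly monthly visits (about 9 scores per subject), self-reported disease
onset averaging about -658 days (SD 456) before trial start, baseline ALSFRS
near 33 declining about -0.025 points/day, heavy-tailed (t with 3 df)
measurement noise, scores bounded in [0, 40], and a one-year endpoint visit
landing near day 387 (SD 24).

Every generated quantity is returned twice: as an observable
:class:`~alsprog.cohort.Cohort` and as a hidden ground-truth table of the
per-subject intercepts, slopes and classes plus the hyperparameters used --
so models can be validated by parameter recovery rather than eyeballing.

Bounded scores are produced by *rejection-resampling the noise term* (never
hard clipping), which makes the generator's observation model exactly the
renormalised truncated-t density that inference assumes.

Onset anchors are never generated here: the anchor is a modelling assumption,
added downstream by :func:`alsprog.cohort.add_onset_anchor`.  The generator
can make that assumption deliberately false (``onset_score < 40``) to study
anchor-induced bias: the true course is then piecewise linear, declining
slowly from ``(onset_time, onset_score)`` to the trial baseline before the
steeper trial-period slope takes over -- the curvilinear-progression geometry
under which an anchor at 40 understates the decline rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Cohort,
    SCORE_MAX,
    SCORE_MIN,
    SubjectRecord,
    VisitObservation,
    first_score_after,
)
from .models import t3_ppf

__all__ = ["CohortSimConfig", "GroundTruth", "generate_cohort", "summarize_cohort"]


@dataclass(frozen=True)
class CohortSimConfig:
    """Generator settings; defaults mirror the target placebo population.

    ``slope_means`` holds one entry for a single-class population or two for
    a fast/slow mixture (fast = more negative, listed first); ``class_probs``
    must match in length and sum to one.  ``residual_scale`` is the *scale*
    of the t3 noise (its SD is sqrt(3) times larger).  ``onset_score``, when
    set, declares the true score at disease onset (< 40), violating the
    downstream anchor assumption; baseline intercepts are then capped at
    ``onset_score`` so the pre-trial course is non-increasing.
    ``onset_intercept_corr`` optionally couples earlier onset to lower
    baseline (0 = independent, the default).  ``onset_latest_days`` is the
    upper truncation bound of the onset-time distribution (default 0 =
    "before trial start"); set it negative, e.g. -180, to enforce a
    realistic minimum lag between symptom onset and trial enrolment.
    Without such a floor the anchor-implied decline rate (40 - baseline) /
    |onset| has positive density at onset -> 0 and therefore an infinite
    mean, which makes anchored-bias studies dominated by a handful of
    implausible recent-onset subjects.
    """

    n_subjects: int = 200
    onset_mean_days: float = -658.4
    onset_sd_days: float = 456.0
    onset_latest_days: float = 0.0
    intercept_mean: float = 33.0
    intercept_sd: float = 3.0
    slope_means: tuple[float, ...] = (-0.025,)
    slope_sd: float = 0.01
    class_probs: tuple[float, ...] = (1.0,)
    residual_scale: float = 1.5
    visit_interval_days: float = 30.44
    visit_jitter_days: float = 3.0
    n_visits_mean: float = 9.3
    n_visits_sd: float = 4.5
    endpoint_day_mean: float = 386.7
    endpoint_day_sd: float = 23.7
    dropout_hazard_per_point_of_decline: float = 0.0
    onset_score: float | None = None
    onset_intercept_corr: float = 0.0
    covariate_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.slope_means) != len(self.class_probs):
            raise ValueError("slope_means and class_probs lengths differ")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for name in ("onset_sd_days", "intercept_sd", "slope_sd", "residual_scale",
                     "visit_jitter_days", "n_visits_sd", "endpoint_day_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dropout_hazard_per_point_of_decline < 0:
            raise ValueError("dropout hazard must be >= 0")
        if not -1.0 < self.onset_intercept_corr < 1.0 + 1e-12:
            raise ValueError("onset_intercept_corr must be in (-1, 1]")
        if self.onset_score is not None and not (
                SCORE_MIN < self.onset_score <= SCORE_MAX):
            raise ValueError("onset_score must lie in (0, 40]")
        if self.onset_latest_days > 0.0:
            raise ValueError("onset_latest_days must be <= 0 (before trial start)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["slope_means"] = list(self.slope_means)
        d["class_probs"] = list(self.class_probs)
        d["covariate_effects"] = {k: list(v) for k, v in self.covariate_effects.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["slope_means"] = tuple(d.get("slope_means", (-0.025,)))
        d["class_probs"] = tuple(d.get("class_probs", (1.0,)))
        d["covariate_effects"] = {
            k: tuple(v) for k, v in (d.get("covariate_effects") or {}).items()
        }
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden truth behind a generated cohort."""

    per_subject: pd.DataFrame  # subject_id, intercept, slope, class, onset, dropout_day
    hyperparameters: dict[str, float]

    def to_csv(self, path) -> None:
        self.per_subject.to_csv(path, index=False)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # Counter-derived stream: adding subjects never reshuffles earlier ones.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed % (2 ** 31), spawn_key=(index,)))


def _truncated_normal(rng, mean, sd, lower=-np.inf, upper=np.inf):
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def _truncated_t3_noise(rng, scale, lower, upper):
    """One t3 noise draw such that the score stays in bounds (rejection)."""
    if scale == 0:
        return 0.0
    for _ in range(100_000):
        # inverse-CDF draw of a standard t3, scaled
        e = scale * float(t3_ppf(rng.random()))
        if lower <= e <= upper:
            return e
    raise RuntimeError("bounded-noise rejection sampling failed")


def generate_cohort(config: CohortSimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate an observable cohort plus its hidden ground truth.

    Per subject: a progression class is drawn from ``class_probs``; the
    intercept from N(intercept_mean, intercept_sd^2) truncated to [0, 40];
    the slope from N(class mean, slope_sd^2) truncated to (-inf, 0]; the
    onset time from N(onset_mean, onset_sd^2) truncated above at
    ``onset_latest_days`` (default 0).  Visits
    occur at jittered ~monthly times starting at day 0; scores are
    intercept + slope*t plus bounded t3 noise.  Subjects not lost to dropout
    receive one extra visit near the endpoint day so a first-score-after-365
    endpoint exists.

    With ``dropout_hazard_per_point_of_decline > 0``, each subject's
    follow-up is cut short with per-visit hazard proportional to their rate
    of decline, so fast progressors exit earlier -- the mechanism by which
    subjects who die before one year still inform the fitted model without
    contributing endpoints.
    """
    cfg = config
    subjects = []
    truth_rows = []
    n_classes = len(cfg.slope_means)
    for i in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, i)
        k = int(rng.choice(n_classes, p=cfg.class_probs))
        slope = _truncated_normal(rng, cfg.slope_means[k], cfg.slope_sd, upper=0.0)
        if cfg.onset_score is None:
            onset = _truncated_normal(rng, cfg.onset_mean_days, cfg.onset_sd_days,
                                      upper=cfg.onset_latest_days)
            rho = cfg.onset_intercept_corr
            # optional onset/baseline coupling: earlier onset -> lower intercept
            onset_z = (onset - cfg.onset_mean_days) / max(cfg.onset_sd_days, 1e-12)
            mean_shift = rho * cfg.intercept_sd * onset_z
            icpt = _truncated_normal(
                rng, cfg.intercept_mean + mean_shift,
                cfg.intercept_sd * math.sqrt(max(1.0 - rho * rho, 0.0)),
                lower=SCORE_MIN, upper=SCORE_MAX)
        else:
            # anchor-violating mode: the true disease course is piecewise
            # linear -- a slow pre-trial decline from (onset, onset_score)
            # down to the trial baseline, then the drawn trial-period slope.
            # Trial-window visits depend only on (intercept, slope); the
            # intercept is capped at onset_score so the pre-trial segment is
            # non-increasing, and the violated true onset score (< 40) is
            # recorded in the ground truth.
            onset = _truncated_normal(rng, cfg.onset_mean_days,
                                      cfg.onset_sd_days,
                                      upper=cfg.onset_latest_days)
            icpt = _truncated_normal(rng, cfg.intercept_mean, cfg.intercept_sd,
                                     lower=SCORE_MIN, upper=cfg.onset_score)

        covariates: dict[str, float] = {}
        for name, (eff_a, eff_b) in cfg.covariate_effects.items():
            x = rng.standard_normal()
            covariates[name] = x
            icpt = float(np.clip(icpt + eff_a * x, SCORE_MIN, SCORE_MAX))
            slope = min(slope + eff_b * x, 0.0)

        n_visits = max(1, int(round(rng.normal(cfg.n_visits_mean, cfg.n_visits_sd))))
        times = [0.0]
        for j in range(1, n_visits):
            t = j * cfg.visit_interval_days + rng.normal(0, cfg.visit_jitter_days)
            if t > 0:
                times.append(t)
        times = sorted(set(times))

        # decline-linked dropout: hazard per visit grows with |slope| (points/day
        # of decline scaled to per-month decline)
        dropout_day = math.inf
        if cfg.dropout_hazard_per_point_of_decline > 0:
            monthly_decline = -slope * 30.44
            hazard = min(cfg.dropout_hazard_per_point_of_decline * monthly_decline, 0.95)
            for t in times[1:]:
                if rng.random() < hazard:
                    dropout_day = t
                    break
        times = [t for t in times if t < dropout_day]

        if math.isinf(dropout_day):
            endpoint_t = _truncated_normal(rng, cfg.endpoint_day_mean,
                                           cfg.endpoint_day_sd, lower=365.0)
            times = sorted(set(times + [endpoint_t]))

        visits = []
        for t in times:
            loc = icpt + slope * t
            noise = _truncated_t3_noise(rng, cfg.residual_scale,
                                        SCORE_MIN - loc, SCORE_MAX - loc)
            visits.append(VisitObservation(time_days=t, score=loc + noise))
        subjects.append(SubjectRecord(
            subject_id=f"S{i:04d}", onset_time_days=onset,
            visits=tuple(visits), covariates=covariates))
        truth_rows.append({
            "subject_id": f"S{i:04d}", "intercept": icpt, "slope": slope,
            "progression_class": k, "onset_time_days": onset,
            "true_onset_score": (SCORE_MAX if cfg.onset_score is None
                                 else cfg.onset_score),
            "dropout_day": dropout_day,
            **{f"x_{name}": covariates[name] for name in covariates},
        })

    hyper = {
        "intercept_mean": cfg.intercept_mean, "intercept_sd": cfg.intercept_sd,
        "slope_sd": cfg.slope_sd, "residual_scale": cfg.residual_scale,
        **{f"slope_mean_{k}": m for k, m in enumerate(cfg.slope_means)},
        **{f"class_prob_{k}": p for k, p in enumerate(cfg.class_probs)},
    }
    cohort = Cohort(subjects=tuple(subjects),
                    covariate_names=tuple(cfg.covariate_effects))
    return cohort, GroundTruth(per_subject=pd.DataFrame(truth_rows),
                               hyperparameters=hyper)


def summarize_cohort(cohort: Cohort, endpoint_day: float = 365.0) -> pd.DataFrame:
    """Demographic summary mirroring the study-population table.

    Counts, onset mean/SD, visits-per-subject mean/SD, score range, and the
    fraction of subjects with an observable endpoint (a real visit at or
    after ``endpoint_day``).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    onsets = np.asarray([s.onset_time_days for s in cohort
                         if s.onset_time_days is not None], dtype=float)
    nvisits = np.asarray([len(s.observed_visits) for s in cohort], dtype=float)
    scores = np.asarray([v.score for s in cohort for v in s.observed_visits])
    has_endpoint = np.asarray(
        [first_score_after(s, endpoint_day) is not None for s in cohort])
    rows = {
        "n_subjects": len(cohort),
        "onset_mean_days": onsets.mean() if len(onsets) else math.nan,
        "onset_sd_days": onsets.std(ddof=1) if len(onsets) > 1 else 0.0,
        "visits_mean": nvisits.mean(),
        "visits_sd": nvisits.std(ddof=1) if len(nvisits) > 1 else 0.0,
        "score_min": scores.min(),
        "score_max": scores.max(),
        "endpoint_available_fraction": has_endpoint.mean(),
    }
    return pd.DataFrame([rows])
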