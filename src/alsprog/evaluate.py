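"""Posterior predictive evaluation: endpoint prediction, posterior MSE,
cross-validation, repeated sub-sampling, and covariate screening.

The endpoint is a subject's first ALSFRS score at or after day 365 from
trial start.  Because models are Bayesian, the cross-validation mean squared
error is itself a posterior distribution: prediction draw *s* for every
validation subject comes from posterior iteration *s*, and

    MSE_s = mean_i (prediction_{i,s} - observed_i)^2 ,

so the MSE draws inherit the joint posterior uncertainty.

The default cross-validation design is *in-sample with held-out endpoint*:
a validation subject's early-window visits are part of the fit (the subject
has its own intercept/slope posterior, shrunk toward the population), while
every post-365-day visit is withheld from the fitted data.  A fully
out-of-sample mode (subject never fitted; prediction through the
hyperparameter posterior only) is available via ``mode="marginal"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    SCORE_MAX,
    SCORE_MIN,
    SubjectRecord,
    complete_case_subset,
    first_score_after,
    normalize_covariates,
    apply_normalization,
    truncate_window,
    ValidationError,
)
from .inference import McmcSettings, PosteriorSamples, dic, fit
from .models import ModelSpec, _t3_cdf, t3_ppf
from scipy.stats import norm as _norm

__all__ = [
    "PredictiveDistribution",
    "EvaluationResult",
    "predict_score",
    "predict_slope",
    "posterior_mse",
    "interval_coverage",
    "cross_validate",
    "repeated_cv",
    "covariate_screen",
]


@dataclass(frozen=True)
class PredictiveDistribution:
    """Posterior predictive score draws for one subject at one target time."""

    subject_id: str
    target_time_days: float
    draws: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", d)
        if np.any((d < SCORE_MIN) | (d > SCORE_MAX)):
            raise ValueError("predictive draws outside the score bounds")

    def mean(self) -> float:
        return float(self.draws.mean())

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed predictive interval."""
        alpha = (1.0 - level) / 2.0
        lo, hi = np.percentile(self.draws, [100 * alpha, 100 * (1 - alpha)])
        return float(lo), float(hi)


def predict_score(samples: PosteriorSamples, subject: SubjectRecord | str,
                  target_time: float, seed: int = 0,
                  mode: str = "in-sample") -> PredictiveDistribution:
    """Posterior predictive distribution of the score at ``target_time``.

    One predicted value per posterior draw: the subject's linear trajectory
    evaluated at the target time plus bounded observation noise.  With
    ``mode="marginal"`` the subject need not have been fitted: the
    per-subject intercept and slope are drawn from their population
    (hyperparameter) distribution instead.
    """
    if not np.isfinite(target_time):
        raise ValueError("target_time must be finite")
    sid = subject if isinstance(subject, str) else subject.subject_id
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed % (2 ** 31), spawn_key=(abs(hash(sid)) % (2 ** 31),)))
    spec = samples.spec
    lo, hi = spec.score_bounds
    if mode == "in-sample":
        j = samples.subject_index(sid)
        a = samples.stacked("a")[:, j]
        b = samples.stacked("b")[:, j]
    elif mode == "marginal":
        a, b = _marginal_subject_draws(samples, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sigma = np.sqrt(samples.stacked("sigma2"))
    loc = a + b * target_time
    # bounded noise by inverse CDF, one uniform per posterior draw
    u = rng.random(loc.shape)
    zl = (lo - loc) / sigma
    zu = (hi - loc) / sigma
    if spec.likelihood == "t3":
        Fl, Fu = _t3_cdf(zl), _t3_cdf(zu)
        z = t3_ppf(np.clip(Fl + u * (Fu - Fl), 1e-12, 1 - 1e-12))
    else:
        Fl, Fu = _norm.cdf(zl), _norm.cdf(zu)
        z = _norm.ppf(np.clip(Fl + u * (Fu - Fl), 1e-12, 1 - 1e-12))
    draws = np.clip(loc + sigma * z, lo, hi)
    return PredictiveDistribution(subject_id=sid, target_time_days=float(target_time),
                                  draws=draws)


def _marginal_subject_draws(samples: PosteriorSamples, rng):
    """Draw a new subject's intercept/slope from the hyperparameter posterior."""
    spec = samples.spec
    lo, hi = spec.score_bounds
    s0 = np.sqrt(samples.stacked("sigma0_2"))
    s1 = np.sqrt(samples.stacked("sigma1_2"))
    if spec.has_covariate:
        raise ValueError("marginal prediction with a covariate model requires "
                         "the subject's covariate; fit the subject instead")
    if spec.kind == "mixture":
        p0 = samples.stacked("p0")
        lam1 = samples.stacked("lambda1")
        c = samples.stacked("c")
        pi1 = samples.stacked("pi1")
        fast = rng.random(len(pi1)) < pi1
        b_mean = np.where(fast, lam1, lam1 + c)
    else:
        p0 = samples.stacked("p0")
        b_mean = samples.stacked("p1")
    a = _tn_draws(rng, p0, s0, lo, hi)
    b = _tn_draws(rng, b_mean, s1, -np.inf, 0.0)
    return a, b


def _tn_draws(rng, mean, sd, lower, upper):
    zl = (lower - mean) / sd if np.isfinite(lower) else np.full_like(mean, -np.inf)
    zu = (upper - mean) / sd if np.isfinite(upper) else np.full_like(mean, np.inf)
    Fl, Fu = _norm.cdf(zl), _norm.cdf(zu)
    u = Fl + rng.random(np.shape(mean)) * (Fu - Fl)
    return mean + sd * _norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))


def predict_slope(samples: PosteriorSamples, subject_id: str) -> np.ndarray:
    """Posterior draws of a fitted subject's decline rate (points/day)."""
    j = samples.subject_index(subject_id)
    return samples.stacked("b")[:, j]


def posterior_mse(predictions, observed) -> np.ndarray:
    """Per-draw mean squared prediction error over a validation set.

    Draw *s* of the result uses prediction draw *s* of every subject, so the
    output is a sample from the posterior distribution of the MSE.
    """
    if len(predictions) != len(observed):
        raise ValueError("predictions and observed lengths differ")
    if len(predictions) == 0:
        raise ValueError("empty validation set")
    if len({np.asarray(p.draws).shape[0] for p in predictions}) != 1:
        raise ValueError("predictions carry differing draw counts")
    mat = np.stack([np.asarray(p.draws, dtype=float) for p in predictions])
    obs = np.asarray(observed, dtype=float)[:, None]
    return np.mean((mat - obs) ** 2, axis=0)


@dataclass
class EvaluationResult:
    """One train/validation split evaluated for one model."""

    spec: ModelSpec
    training_ids: list[str]
    validation_ids: list[str]
    seed: int
    predictions: list[PredictiveDistribution]
    observed: list[float]
    mse_draws: np.ndarray
    samples: PosteriorSamples | None = None

    @property
    def mean_mse(self) -> float:
        return float(self.mse_draws.mean())

    @property
    def mean_bias(self) -> float:
        """Mean over validation subjects of predictive mean minus observed."""
        return float(np.mean([p.mean() - o for p, o in
                              zip(self.predictions, self.observed)]))

    def coverage(self, level: float = 0.95) -> float:
        return interval_coverage(self, level)


def interval_coverage(result: EvaluationResult, level: float) -> float:
    """Fraction of validation subjects whose observed endpoint falls inside
    their equal-tailed ``level`` predictive interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    hits = 0
    for p, o in zip(result.predictions, result.observed):
        lo, hi = p.interval(level)
        if lo <= o <= hi:
            hits += 1
    return hits / len(result.predictions)


def _eligible_ids(cohort: Cohort, endpoint_day: float) -> list[str]:
    return [s.subject_id for s in cohort
            if first_score_after(s, endpoint_day) is not None]


def cross_validate(cohort: Cohort, specs, window_days: float = 91.0,
                   val_size: int | None = None, val_fraction: float = 0.1,
                   settings: McmcSettings | None = None, seed: int = 0,
                   endpoint_day: float = 365.0,
                   mode: str = "in-sample") -> dict[str, EvaluationResult]:
    """Single train/validation split, evaluated for each model spec.

    Validation subjects are drawn (seeded) from those with an observable
    endpoint; the identical split is reused for every spec.  All subjects'
    visits are truncated to ``window_days`` for fitting, so no validation
    endpoint -- indeed nothing past the window -- ever enters the fitted
    data.  Training-only subjects whose visits all fall outside the window
    are dropped.

    Returns ``{spec_label: EvaluationResult}`` where labels are the spec
    kinds (suffixed when duplicated).
    """
    specs = list(specs)
    settings = settings or McmcSettings()
    eligible = _eligible_ids(cohort, endpoint_day)
    if val_size is None:
        val_size = max(1, int(round(val_fraction * len(eligible))))
    if len(eligible) < val_size:
        raise ValidationError(
            f"only {len(eligible)} subjects have an endpoint; "
            f"cannot hold out {val_size}")
    rng = np.random.default_rng(seed % (2 ** 31))
    val_ids = set(rng.choice(eligible, size=val_size, replace=False).tolist())

    fit_subjects: list[SubjectRecord] = []
    observed: dict[str, tuple[float, float]] = {}
    for s in cohort:
        if s.subject_id in val_ids:
            observed[s.subject_id] = first_score_after(s, endpoint_day)
            fit_subjects.append(truncate_window(s, window_days))
        else:
            try:
                fit_subjects.append(truncate_window(s, window_days))
            except ValidationError:
                continue
    if mode == "marginal":
        fit_subjects = [s for s in fit_subjects if s.subject_id not in val_ids]
    fit_cohort = Cohort(subjects=tuple(fit_subjects),
                        covariate_names=cohort.covariate_names)
    # leakage guard: nothing in the fitted data may sit past the window
    assert all(v.is_anchor or v.time_days <= window_days
               for s in fit_cohort for v in s.visits)

    training_ids = [s.subject_id for s in fit_subjects
                    if s.subject_id not in val_ids]
    results: dict[str, EvaluationResult] = {}
    for spec in specs:
        label = spec.kind
        if spec.recall_error != "none":
            label += f"+recall_{spec.recall_error}"
        if label in results:
            label += f"#{len(results)}"
        samples = fit(spec, fit_cohort, settings)
        preds, obs_vals = [], []
        for sid in sorted(val_ids):
            t_obs, y_obs = observed[sid]
            pred_mode = "marginal" if mode == "marginal" else "in-sample"
            preds.append(predict_score(samples, sid, t_obs, seed=seed,
                                       mode=pred_mode))
            obs_vals.append(y_obs)
        results[label] = EvaluationResult(
            spec=spec, training_ids=training_ids,
            validation_ids=sorted(val_ids), seed=seed, predictions=preds,
            observed=obs_vals, mse_draws=posterior_mse(preds, obs_vals),
            samples=samples)
    return results


def repeated_cv(cohort: Cohort, specs, n_replicates: int = 25,
                window_days: float = 91.0, val_size: int | None = None,
                val_fraction: float = 0.1,
                settings: McmcSettings | None = None, seed: int = 0,
                endpoint_day: float = 365.0) -> pd.DataFrame:
    """Repeated random sub-sampling cross-validation.

    Runs ``n_replicates`` independent seeded splits and tabulates the
    posterior-mean MSE per model per replicate, plus all pairwise
    differences (columns ``"A - B"``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for r in range(n_replicates):
        res = cross_validate(cohort, specs, window_days=window_days,
                             val_size=val_size, val_fraction=val_fraction,
                             settings=settings, seed=seed + 1000 * r + 1,
                             endpoint_day=endpoint_day)
        row = {"replicate": r, "seed": seed + 1000 * r + 1}
        for label, er in res.items():
            row[f"mse_{label}"] = er.mean_mse
        labels = list(res)
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                row[f"mse_{la} - mse_{lb}"] = res[la].mean_mse - res[lb].mean_mse
        rows.append(row)
    return pd.DataFrame(rows)


def covariate_screen(cohort: Cohort, covariate_name: str,
                     n_replicates: int = 100, subset_size: int = 300,
                     val_size: int = 30, window_days: float = 91.0,
                     settings: McmcSettings | None = None, seed: int = 0,
                     endpoint_day: float = 365.0) -> dict:
    """Does a covariate improve onset-anchored predictions?

    Each replicate draws ``subset_size`` complete cases, splits off
    ``val_size`` validation subjects, fits the onset-anchored model with and
    without the covariate on the identical split, and records the percentage
    MSE reduction ((without - with)/without * 100, posterior-mean MSEs) and
    the DIC change.  Returns the median and IQR of the percentage reduction
    and the mean DIC adjustment over replicates.
    """
    settings = settings or McmcSettings()
    complete = complete_case_subset(cohort, covariate_name)
    if len(complete) < subset_size:
        raise ValidationError(
            f"only {len(complete)} complete cases for {covariate_name!r}; "
            f"need {subset_size}")
    base_spec = ModelSpec(kind="onset_anchored")
    cov_spec = ModelSpec(kind="onset_anchored_covariate",
                         covariate_name=covariate_name)
    reductions, ddics = [], []
    for r in range(n_replicates):
        rng = np.random.default_rng((seed + 7919 * r + 1) % (2 ** 31))
        ids = rng.choice([s.subject_id for s in complete], size=subset_size,
                         replace=False)
        chosen = Cohort(subjects=tuple(s for s in complete
                                       if s.subject_id in set(ids)),
                        covariate_names=complete.covariate_names)
        eligible = _eligible_ids(chosen, endpoint_day)
        if len(eligible) < val_size:
            raise ValidationError(
                f"replicate {r}: only {len(eligible)} eligible subjects")
        val_ids = set(rng.choice(eligible, size=val_size, replace=False).tolist())
        train = Cohort(subjects=tuple(s for s in chosen
                                      if s.subject_id not in val_ids),
                       covariate_names=chosen.covariate_names)
        _, table = normalize_covariates(train, [covariate_name])
        normed = apply_normalization(chosen, table)

        res = _screen_split(normed, val_ids, [base_spec, cov_spec],
                            window_days, settings, seed + 7919 * r + 1,
                            endpoint_day)
        mse_without = res["onset_anchored"].mean_mse
        mse_with = res["onset_anchored_covariate"].mean_mse
        reductions.append((mse_without - mse_with) / mse_without * 100.0)
        ddics.append(dic(res["onset_anchored_covariate"].samples)
                     - dic(res["onset_anchored"].samples))
    reductions = np.asarray(reductions)
    q25, q75 = np.percentile(reductions, [25, 75])
    return {
        "covariate": covariate_name,
        "median_pct_mse_reduction": float(np.median(reductions)),
        "iqr_pct_mse_reduction": float(q75 - q25),
        "mean_dic_adjustment": float(np.mean(ddics)),
        "pct_mse_reductions": reductions,
    }


def _screen_split(cohort: Cohort, val_ids: set, specs, window_days,
                  settings, seed, endpoint_day):
    """cross_validate with a caller-chosen validation set."""
    fit_subjects, observed = [], {}
    for s in cohort:
        if s.subject_id in val_ids:
            observed[s.subject_id] = first_score_after(s, endpoint_day)
            fit_subjects.append(truncate_window(s, window_days))
        else:
            try:
                fit_subjects.append(truncate_window(s, window_days))
            except ValidationError:
                continue
    fit_cohort = Cohort(subjects=tuple(fit_subjects),
                        covariate_names=cohort.covariate_names)
    results = {}
    for spec in specs:
        samples = fit(spec, fit_cohort, settings)
        preds, obs_vals = [], []
        for sid in sorted(val_ids):
            t_obs, y_obs = observed[sid]
            preds.append(predict_score(samples, sid, t_obs, seed=seed))
            obs_vals.append(y_obs)
        results[spec.kind] = EvaluationResult(
            spec=spec,
            training_ids=[s.subject_id for s in fit_subjects
                          if s.subject_id not in val_ids],
            validation_ids=sorted(val_ids), seed=seed, predictions=preds,
            observed=obs_vals, mse_draws=posterior_mse(preds, obs_vals),
            samples=samples)
    return results
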