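"""Model specifications and log-densities for the hierarchical ALSFRS models.

Four model kinds share a common likelihood: the score for subject *i* at time
*t* follows a non-standardised t distribution with 3 degrees of freedom,

    ALSFRS_i(t) ~ T3(a_i + b_i * t, sigma^2),   truncated to [0, 40],

where ``sigma`` is the t scale parameter (the BUGS precision convention:
``sigma^2`` is the square of the scale, *not* the distribution's variance,
which is ``3 * sigma^2`` for 3 degrees of freedom).  Heavy tails are a
deliberate choice: residuals of per-subject linear fits on ALSFRS data are far
wider-tailed than Gaussian.

The kinds differ only in the prior on the per-subject intercept ``a_i`` in
[0, 40] and slope ``b_i`` in (-inf, 0]:

* ``linear`` -- a_i ~ N(p0, sigma0^2), b_i ~ N(p1, sigma1^2), truncated.
* ``mixture`` -- the slope hypermean is latent: fast progressors have mean
  Lambda1, slow progressors Lambda2 = Lambda1 + c with c >= 0, class weights
  pi ~ Dirichlet(1, 1).  Ordering via c >= 0 removes label switching.
* ``onset_anchored`` -- identical to ``linear``; the only difference is the
  data: every subject gains the artificial onset-anchor observation
  (score 40 at onset time), treated as observed.
* ``onset_anchored_covariate`` -- anchored, with a scalar covariate X_i
  entering both hypermeans: a_i ~ N(p00 + p01 X_i, sigma0^2),
  b_i ~ N(p10 + p11 X_i, sigma1^2).

The optional recall-error extension models recall bias in self-reported onset
time by shifting the anchor time by a latent normal error, either one shared
shift for the whole cohort or one per subject.

Truncation is handled by renormalising each density by its mass on the
interval (not by censoring); all truncated log-pdfs here integrate to one over
their support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import log_ndtr

from .cohort import Cohort, SCORE_MAX, SCORE_MIN

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "trunc_t_logpdf",
    "trunc_normal_logpdf",
    "joint_log_density",
    "CohortArrays",
]

_LOG_T3_NORM = math.log(2.0 / (math.pi * math.sqrt(3.0)))
_SQRT3 = math.sqrt(3.0)


def _t3_logpdf(z):
    """Log-pdf of the standard t distribution with 3 df (closed form)."""
    return _LOG_T3_NORM - 2.0 * np.log1p(np.square(z) / 3.0)


def _t3_cdf(z):
    """CDF of the standard t with 3 df (closed form)."""
    z = np.asarray(z, dtype=float)
    u = z / _SQRT3
    out = 0.5 + (u / (1.0 + u * u) + np.arctan(u)) / math.pi
    return np.where(np.isposinf(z), 1.0, np.where(np.isneginf(z), 0.0, out))


def t3_ppf(q):
    """Quantile function of the standard t with 3 df (via scipy)."""
    return stats.t.ppf(q, df=3)


def trunc_t_logpdf(y, location, scale, df: int = 3,
                   lower: float = SCORE_MIN, upper: float = SCORE_MAX):
    """Log-density of a t distribution truncated (renormalised) to an interval.

    Parameters follow the non-standardised convention: ``scale`` multiplies a
    standard t variate with ``df`` degrees of freedom.  Values outside
    ``[lower, upper]`` have log-density ``-inf``.  Broadcasts over arrays.
    """
    y = np.asarray(y, dtype=float)
    location = np.asarray(location, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(location)):
        raise ValueError("non-finite y or location")
    if np.any(~np.isfinite(scale)) or np.any(scale <= 0):
        raise ValueError("scale must be finite and > 0")
    if not lower < upper:
        raise ValueError("lower must be < upper")
    z = (y - location) / scale
    if df == 3:
        lp = _t3_logpdf(z) - np.log(scale)
        mass = _t3_cdf((upper - location) / scale) - _t3_cdf((lower - location) / scale)
    else:
        lp = stats.t.logpdf(z, df=df) - np.log(scale)
        mass = stats.t.cdf((upper - location) / scale, df=df) - stats.t.cdf(
            (lower - location) / scale, df=df
        )
    out = lp - np.log(np.maximum(mass, 1e-300))
    return np.where((y < lower) | (y > upper), -np.inf, out)


def _log_norm_mass(alpha, beta):
    """log(Phi(beta) - Phi(alpha)) computed stably for array arguments."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    # Symmetry: reflect so that the interval sits in the left tail.  An
    # infinite bound of either sign makes alpha + beta indeterminate; the
    # reflection choice is then irrelevant, so substitute 0 to keep the
    # comparison silent.
    with np.errstate(invalid="ignore"):
        flip = np.nan_to_num(alpha + beta, nan=0.0) > 0
    a = np.where(flip, -beta, alpha)
    b = np.where(flip, -alpha, beta)
    lb = log_ndtr(b)
    la = log_ndtr(a)
    with np.errstate(invalid="ignore"):
        diff = -np.expm1(la - lb)
    return lb + np.log(np.maximum(diff, 1e-300))


def trunc_normal_logpdf(y, mean, sd, lower=-np.inf, upper=np.inf):
    """Log-density of a normal truncated (renormalised) to ``[lower, upper]``."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(mean)):
        raise ValueError("non-finite y or mean")
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        raise ValueError("sd must be finite and > 0")
    z = (y - mean) / sd
    lp = -0.5 * z * z - 0.5 * math.log(2.0 * math.pi) - np.log(sd)
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    both_inf = np.isneginf(lo) & np.isposinf(hi)
    log_mass = np.where(
        both_inf, 0.0, _log_norm_mass((lo - mean) / sd, (hi - mean) / sd)
    )
    out = lp - log_mass
    return np.where((y < lo) | (y > hi), -np.inf, out)


# --- configuration ----------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings shared by every model kind.

    Defaults encode weakly informative clinical priors: trial entrants start
    near ALSFRS 33, and the population decline rate is around -0.025 points
    per day (about -0.9 per month on the revised scale).  Variance components
    receive the vague inverse-gamma(0.001, 0.001) prior, i.e. each precision
    1/sigma^2 ~ Gamma(0.001, rate 0.001).
    """

    p0_mean: float = 33.0       # intercept hypermean prior: N(33, 3^2)
    p0_sd: float = 3.0
    p1_mean: float = -0.025     # slope hypermean prior: N(-0.025, 0.3^2), per day
    p1_sd: float = 0.3
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001
    covariate_coef_sd: float = 100.0   # p01, p11 ~ N(0, 100^2)
    mixture_sep_sd: float = 10.0       # c ~ half-normal(sd 10): N(0, 100) on [0, inf)
    dirichlet_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("p0_sd", "p1_sd", "variance_prior_shape",
                     "variance_prior_rate", "covariate_coef_sd", "mixture_sep_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


ModelKind = Literal["linear", "mixture", "onset_anchored", "onset_anchored_covariate"]
RecallError = Literal["none", "shared", "individual"]


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, with all prior hyperparameters.

    ``likelihood`` exists so the heavy-tailed t3 observation model can be
    compared against a truncated-normal one (a comparator kept for model
    criticism, not a production mode).
    """

    kind: ModelKind = "onset_anchored"
    priors: PriorConfig = field(default_factory=PriorConfig)
    covariate_name: str | None = None
    recall_error: RecallError = "none"
    likelihood: Literal["t3", "normal"] = "t3"
    likelihood_df: int = 3
    score_bounds: tuple[float, float] = (SCORE_MIN, SCORE_MAX)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "mixture", "onset_anchored",
                             "onset_anchored_covariate"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if (self.kind == "onset_anchored_covariate") != (self.covariate_name is not None):
            raise ValueError("covariate_name is required iff kind is "
                             "'onset_anchored_covariate'")
        if self.recall_error not in ("none", "shared", "individual"):
            raise ValueError(f"unknown recall_error {self.recall_error!r}")
        if self.recall_error != "none" and not self.anchored:
            raise ValueError("recall_error requires an onset-anchored kind")

    @property
    def anchored(self) -> bool:
        return self.kind in ("onset_anchored", "onset_anchored_covariate")

    @property
    def has_covariate(self) -> bool:
        return self.kind == "onset_anchored_covariate"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["priors"] = asdict(self.priors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        pri = d.pop("priors", {})
        if isinstance(pri.get("dirichlet_weights"), list):
            pri["dirichlet_weights"] = tuple(pri["dirichlet_weights"])
        if isinstance(d.get("score_bounds"), list):
            d["score_bounds"] = tuple(d["score_bounds"])
        return cls(priors=PriorConfig(**pri), **d)


# --- flattened cohort arrays ------------------------------------------------

class CohortArrays:
    """Flat numpy views of a cohort for fast likelihood evaluation.

    Observations are concatenated over subjects; ``subj`` maps each
    observation to its subject index.  Anchor observations are flagged so the
    recall-error extension can shift their times.
    """

    def __init__(self, cohort: Cohort, covariate_name: str | None = None):
        self.subject_ids = [s.subject_id for s in cohort.subjects]
        self.n_subjects = len(self.subject_ids)
        subj, time, score, anchor = [], [], [], []
        for i, s in enumerate(cohort.subjects):
            for v in s.visits:
                subj.append(i)
                time.append(v.time_days)
                score.append(v.score)
                anchor.append(v.is_anchor)
        self.subj = np.asarray(subj, dtype=np.intp)
        self.time = np.asarray(time, dtype=float)
        self.score = np.asarray(score, dtype=float)
        self.anchor = np.asarray(anchor, dtype=bool)
        self.n_obs = len(self.subj)
        self.obs_per_subject = np.bincount(self.subj, minlength=self.n_subjects)
        if covariate_name is not None:
            x = np.asarray(
                [s.covariates.get(covariate_name, np.nan) for s in cohort.subjects],
                dtype=float,
            )
            if np.any(np.isnan(x)):
                bad = [self.subject_ids[i] for i in np.where(np.isnan(x))[0][:5]]
                raise ValueError(
                    f"covariate {covariate_name!r} missing for subjects {bad}; "
                    "use complete_case_subset first"
                )
            self.covariate = x
        else:
            self.covariate = None

    def times_with_recall_shift(self, delta):
        """Observation times with anchor times shifted by the recall error.

        ``delta`` is a scalar (shared) or per-subject vector (individual).
        """
        if delta is None:
            return self.time
        shift = np.asarray(delta, dtype=float)
        if shift.ndim == 1:
            shift = shift[self.subj]
        return np.where(self.anchor, self.time + shift, self.time)

    def segment_sum(self, values):
        """Sum observation-level values into per-subject totals."""
        return np.bincount(self.subj, weights=values, minlength=self.n_subjects)


# --- joint log density ------------------------------------------------------

def _invgamma_logpdf(x, shape, rate):
    """log p(x) for x ~ Inv-Gamma(shape, rate), i.e. 1/x ~ Gamma(shape, rate)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(
        np.sum(shape * math.log(rate) - math.lgamma(shape)
               - (shape + 1.0) * np.log(x) - rate / x)
    )


def mixture_slope_logprior(b, lambda1, c, pi1, sigma1):
    """Per-subject log-prior of slopes under the two-class mixture.

    Marginalises the latent class indicator: the slope prior is a two-component
    mixture of normals truncated to (-inf, 0], with fast mean ``lambda1``
    (weight ``pi1``) and slow mean ``lambda1 + c``.
    """
    lp_fast = trunc_normal_logpdf(b, lambda1, sigma1, upper=0.0) + math.log(max(pi1, 1e-300))
    lp_slow = trunc_normal_logpdf(b, lambda1 + c, sigma1, upper=0.0) + math.log(
        max(1.0 - pi1, 1e-300)
    )
    hi = np.maximum(lp_fast, lp_slow)
    both_inf = np.isneginf(hi)
    hi_safe = np.where(both_inf, 0.0, hi)
    out = hi_safe + np.log(np.exp(lp_fast - hi_safe) + np.exp(lp_slow - hi_safe))
    return np.where(both_inf, -np.inf, out)


def observation_loglik(spec: ModelSpec, data: CohortArrays, params: dict,
                       per_subject: bool = False):
    """Truncated-likelihood term only (used for the deviance in DIC).

    Returns the scalar total, or per-subject totals with ``per_subject``.
    """
    a = np.asarray(params["a"], dtype=float)
    b = np.asarray(params["b"], dtype=float)
    sigma = math.sqrt(float(params["sigma2"]))
    delta = params.get("delta") if spec.recall_error != "none" else None
    t = data.times_with_recall_shift(delta)
    mean = a[data.subj] + b[data.subj] * t
    lo, hi = spec.score_bounds
    if spec.likelihood == "t3":
        ll = trunc_t_logpdf(data.score, mean, sigma, df=spec.likelihood_df,
                            lower=lo, upper=hi)
    else:
        ll = trunc_normal_logpdf(data.score, mean, sigma, lower=lo, upper=hi)
    if per_subject:
        return data.segment_sum(ll)
    return float(np.sum(ll))


def joint_log_density(spec: ModelSpec, cohort_or_arrays, params: dict) -> float:
    """Unnormalised log posterior density of a full parameter assignment.

    ``params`` must contain per-subject arrays ``a`` (intercepts) and ``b``
    (slopes) plus every hyperparameter the spec implies:

    * always: ``sigma2``, ``sigma0_2``, ``sigma1_2``
    * linear / anchored: ``p0``, ``p1``
    * covariate kind: ``p00``, ``p01``, ``p10``, ``p11``
    * mixture: ``lambda1``, ``c``, ``pi1``, ``sigma_l1_2`` (plus ``p0`` for
      the intercept hypermean, shared with the linear model)
    * recall error: ``delta`` (scalar or per-subject), ``sigma_d_2``

    A parameter outside its support yields ``-inf`` rather than raising.
    """
    data = (cohort_or_arrays if isinstance(cohort_or_arrays, CohortArrays)
            else CohortArrays(cohort_or_arrays, spec.covariate_name))
    if spec.anchored and not np.any(data.anchor):
        raise ValueError("anchored model requires an anchored cohort")
    pri = spec.priors
    a = np.asarray(params["a"], dtype=float)
    b = np.asarray(params["b"], dtype=float)
    lo, hi = spec.score_bounds

    # support checks -> -inf
    variances = [params["sigma2"], params["sigma0_2"], params["sigma1_2"]]
    if spec.kind == "mixture":
        variances.append(params["sigma_l1_2"])
    if spec.recall_error != "none":
        variances.append(params["sigma_d_2"])
    if any((not np.isfinite(v)) or v <= 0 for v in variances):
        return -np.inf
    if np.any(a < lo) or np.any(a > hi) or np.any(b > 0):
        return -np.inf
    if spec.kind == "mixture":
        if params["c"] < 0 or not (0.0 <= params["pi1"] <= 1.0):
            return -np.inf

    total = observation_loglik(spec, data, params)

    sigma0 = math.sqrt(float(params["sigma0_2"]))
    sigma1 = math.sqrt(float(params["sigma1_2"]))

    # per-subject priors
    if spec.has_covariate:
        a_mean = params["p00"] + params["p01"] * data.covariate
        b_mean = params["p10"] + params["p11"] * data.covariate
        total += float(np.sum(trunc_normal_logpdf(a, a_mean, sigma0, lower=lo, upper=hi)))
        total += float(np.sum(trunc_normal_logpdf(b, b_mean, sigma1, upper=0.0)))
        total += float(stats.norm.logpdf(params["p00"], pri.p0_mean, pri.p0_sd))
        total += float(stats.norm.logpdf(params["p10"], pri.p1_mean, pri.p1_sd))
        total += float(stats.norm.logpdf(params["p01"], 0.0, pri.covariate_coef_sd))
        total += float(stats.norm.logpdf(params["p11"], 0.0, pri.covariate_coef_sd))
    elif spec.kind == "mixture":
        total += float(np.sum(trunc_normal_logpdf(a, params["p0"], sigma0,
                                                  lower=lo, upper=hi)))
        total += float(np.sum(mixture_slope_logprior(
            b, params["lambda1"], params["c"], params["pi1"], sigma1)))
        total += float(stats.norm.logpdf(params["p0"], pri.p0_mean, pri.p0_sd))
        sigma_l1 = math.sqrt(float(params["sigma_l1_2"]))
        total += float(stats.norm.logpdf(params["lambda1"], 0.0, sigma_l1))
        # c ~ half-normal; pi ~ Dirichlet(1,1) i.e. pi1 ~ Uniform(0,1): constant
        total += float(trunc_normal_logpdf(params["c"], 0.0, pri.mixture_sep_sd,
                                           lower=0.0))
        w1, w2 = pri.dirichlet_weights
        total += float(stats.beta.logpdf(np.clip(params["pi1"], 1e-12, 1 - 1e-12),
                                         w1, w2))
        total += _invgamma_logpdf(params["sigma_l1_2"], pri.variance_prior_shape,
                                  pri.variance_prior_rate)
    else:  # linear / onset_anchored
        total += float(np.sum(trunc_normal_logpdf(a, params["p0"], sigma0,
                                                  lower=lo, upper=hi)))
        total += float(np.sum(trunc_normal_logpdf(b, params["p1"], sigma1, upper=0.0)))
        total += float(stats.norm.logpdf(params["p0"], pri.p0_mean, pri.p0_sd))
        total += float(stats.norm.logpdf(params["p1"], pri.p1_mean, pri.p1_sd))

    for v in ("sigma2", "sigma0_2", "sigma1_2"):
        total += _invgamma_logpdf(params[v], pri.variance_prior_shape,
                                  pri.variance_prior_rate)

    if spec.recall_error != "none":
        sigma_d = math.sqrt(float(params["sigma_d_2"]))
        total += float(np.sum(stats.norm.logpdf(np.atleast_1d(params["delta"]),
                                                0.0, sigma_d)))
        total += _invgamma_logpdf(params["sigma_d_2"], pri.variance_prior_shape,
                                  pri.variance_prior_rate)

    return float(total)


def mixture_class_probabilities(b, lambda1, c, pi1, sigma1):
    """Posterior probability each subject is a fast progressor, given slopes.

    Computed from the marginalised mixture: P(fast | b_i) by Bayes' rule over
    the two truncated-normal components.
    """
    lp_fast = trunc_normal_logpdf(b, lambda1, sigma1, upper=0.0) + math.log(max(pi1, 1e-300))
    lp_slow = trunc_normal_logpdf(b, lambda1 + c, sigma1, upper=0.0) + math.log(
        max(1.0 - pi1, 1e-300)
    )
    m = np.maximum(lp_fast, lp_slow)
    pf = np.exp(lp_fast - m)
    return pf / (pf + np.exp(lp_slow - m))
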