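"""Posterior sampling for the hierarchical ALSFRS models.

The sampler is an adaptive Metropolis-within-Gibbs scheme over the joint
log-density defined in :mod:`alsprog.models`:

* Per-subject intercepts and slopes are conditionally independent given the
  hyperparameters, so each block updates *all* subjects in one vectorised
  random-walk Metropolis step with per-subject step sizes and per-subject
  accept/reject decisions.
* Scalar hyperparameters use univariate random-walk Metropolis; variance
  components are proposed multiplicatively (random walk on the log scale,
  with the Jacobian term included).
* Proposals that land outside a parameter's support are rejected outright
  (the target density is zero there), which keeps truncation exact.
* Mixture class indicators are marginalised out of the density; per-draw
  class membership probabilities can be recovered afterwards with
  :func:`alsprog.models.mixture_class_probabilities`.

Step sizes adapt towards standard acceptance targets (0.44 for univariate
blocks) by Robbins-Monro during warmup only and are frozen afterwards, so
the post-warmup chain is a valid time-homogeneous Markov chain.

Convergence is summarised by split-R-hat and an autocorrelation-based
effective sample size; any parameter with R-hat above 1.05 flags the result
as non-converged (returned with a warning, never silently).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, anchor_cohort
from .models import (
    CohortArrays,
    ModelSpec,
    joint_log_density,
    mixture_slope_logprior,
    observation_loglik,
    trunc_normal_logpdf,
    trunc_t_logpdf,
)

__all__ = ["McmcSettings", "PosteriorSamples", "fit", "dic",
           "split_rhat", "effective_sample_size"]

_ACCEPT_TARGET = 0.44
_LOG_2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def _invgamma_lp(x, shape, rate):
    if x <= 0:
        return -math.inf
    return (shape * math.log(rate) - math.lgamma(shape)
            - (shape + 1.0) * math.log(x) - rate / x)


def _beta_lp(x, a, b):
    if not 0.0 < x < 1.0:
        return -math.inf
    return ((a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x)
            + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b))


# --- convergence diagnostics ------------------------------------------------

def _split(d: np.ndarray) -> np.ndarray:
    """Split each chain in half: (chain, draw, ...) -> (2*chain, draw//2, ...)."""
    nc, nd = d.shape[0], d.shape[1]
    half = nd // 2
    return d[:, : 2 * half].reshape(nc, 2, half, *d.shape[2:]).reshape(
        2 * nc, half, *d.shape[2:])


def split_rhat(d: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor.

    ``d`` has shape (chain, draw) or (chain, draw, k); the result is scalar
    or length-k.  Values near 1 indicate between-chain agreement.
    """
    x = _split(np.asarray(d, dtype=float))
    n = x.shape[1]
    mean_c = x.mean(axis=1)
    var_c = x.var(axis=1, ddof=1)
    w = var_c.mean(axis=0)
    b = n * mean_c.var(axis=0, ddof=1)
    var_hat = (n - 1.0) / n * w + b / n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(var_hat / w)
    return np.where(w <= 1e-300, 1.0, out)


def effective_sample_size(d: np.ndarray) -> np.ndarray:
    """Effective sample size from chain autocorrelations.

    Uses FFT autocovariances per split chain, combined across chains, with
    Geyer's initial-monotone truncation of the paired autocorrelation sums.
    """
    x = _split(np.asarray(d, dtype=float))
    if x.ndim == 2:
        x = x[:, :, None]
    m, n, k = x.shape
    out = np.empty(k)
    for j in range(k):
        xc = x[:, :, j] - x[:, :, j].mean(axis=1, keepdims=True)
        f = np.fft.rfft(xc, 2 * n, axis=1)
        acov = np.fft.irfft(f * np.conj(f), axis=1)[:, :n].real / n
        w = acov.mean(axis=0)
        b = n * x[:, :, j].mean(axis=1).var(ddof=1) if m > 1 else 0.0
        var_hat = (n - 1.0) / n * w[0] + b / n
        if var_hat <= 1e-300:
            out[j] = float(m * n)
            continue
        rho = 1.0 - (w[0] - w) / var_hat
        # Geyer: sum paired rho while the pair sums stay positive and decreasing
        tau = 1.0
        prev = math.inf
        for t in range(1, n - 1, 2):
            pair = rho[t] + rho[t + 1]
            if pair < 0:
                break
            pair = min(pair, prev)
            prev = pair
            tau += 2.0 * pair
        out[j] = m * n / tau
    return out if d.ndim == 3 else out[0]


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings.

    Defaults (4 chains, 1000 warmup, 1000 draws) suit final reported fits;
    simulation studies in the test-suite use shorter, explicitly stated runs.
    ``thin`` keeps every ``thin``-th post-warmup sweep, useful when nearly
    independent draws are required.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 1000
    seed: int = 0
    thin: int = 1
    init_strategy: str = "ols-jitter"  # or "prior"

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.n_warmup < 0 or self.n_draws < 1 or self.thin < 1:
            raise ValueError("invalid warmup/draws/thin")
        if self.init_strategy not in ("ols-jitter", "prior"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")


@dataclass
class PosteriorSamples:
    """MCMC draws plus the exact fitted cohort and diagnostics.

    ``draws[name]`` has shape ``(chain, draw)`` for scalars and
    ``(chain, draw, n_subjects)`` for per-subject vectors (``a``, ``b``,
    and ``delta`` under individual recall error).  ``lp`` is the joint
    log-density of each kept draw; ``loglik`` its observation-likelihood part.
    """

    spec: ModelSpec
    settings: McmcSettings
    subject_ids: list[str]
    draws: dict[str, np.ndarray]
    lp: np.ndarray
    loglik: np.ndarray
    cohort: Cohort
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"subject {subject_id!r} not in fitted cohort") from None

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened: (chain*draw,) or (chain*draw, n)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def n_kept(self) -> int:
        return self.lp.size

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy draws: columns chain, iteration, parameter, value."""
        rows = []
        for name, d in self.draws.items():
            nc, nd = d.shape[:2]
            chains = np.repeat(np.arange(nc), nd)
            iters = np.tile(np.arange(nd), nc)
            if d.ndim == 2:
                rows.append(pd.DataFrame(
                    {"chain": chains, "iteration": iters, "parameter": name,
                     "value": d.reshape(-1)}))
            else:
                for j, sid in enumerate(self.subject_ids):
                    rows.append(pd.DataFrame(
                        {"chain": chains, "iteration": iters,
                         "parameter": f"{name}[{sid}]", "value": d[:, :, j].reshape(-1)}))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Posterior mean/SD/quantiles with R-hat and ESS per parameter."""
        rows = {}
        for name, d in self.draws.items():
            if d.ndim == 2:
                flat = d.reshape(-1)
                rows[name] = _summary_row(flat)
            else:
                for j, sid in enumerate(self.subject_ids):
                    rows[f"{name}[{sid}]"] = _summary_row(d[:, :, j].reshape(-1))
        out = pd.DataFrame(rows).T
        return out.join(self.diagnostics, how="left")


def _summary_row(flat: np.ndarray) -> pd.Series:
    q = np.percentile(flat, [2.5, 50, 97.5])
    return pd.Series({"mean": flat.mean(), "sd": flat.std(ddof=1),
                      "q2.5": q[0], "median": q[1], "q97.5": q[2]})


# --- initialisation ---------------------------------------------------------

def _ols_init(data: CohortArrays, spec: ModelSpec, rng: np.random.Generator):
    pri = spec.priors
    lo, hi = spec.score_bounds
    lo_c = lo if np.isfinite(lo) else -1e6
    hi_c = hi if np.isfinite(hi) else 1e6
    n = data.n_subjects
    a = np.full(n, pri.p0_mean)
    b = np.full(n, min(pri.p1_mean, -1e-4))
    for i in range(n):
        m = data.subj == i
        t, y = data.time[m], data.score[m]
        if len(t) >= 2 and np.ptp(t) > 0:
            sl, ic = np.polyfit(t, y, 1)
            b[i] = min(sl, -1e-6)
            a[i] = ic
        elif len(t) == 1:
            a[i] = y[0] - b[i] * t[0]
    a = np.clip(a + rng.normal(0, 0.5, n), lo_c + 0.1, hi_c - 0.1)
    b = np.minimum(b * np.exp(rng.normal(0, 0.1, n)), -1e-8)
    return a, b


def _prior_init(data: CohortArrays, spec: ModelSpec, rng: np.random.Generator):
    pri = spec.priors
    lo, hi = spec.score_bounds
    n = data.n_subjects
    a = np.clip(rng.normal(pri.p0_mean, pri.p0_sd, n),
                lo if np.isfinite(lo) else -1e6, hi if np.isfinite(hi) else 1e6)
    b = np.minimum(rng.normal(pri.p1_mean, pri.p1_sd / 10.0, n), -1e-6)
    return a, b


def _init_state(spec: ModelSpec, data: CohortArrays, rng: np.random.Generator,
                fixed: dict, init_strategy: str = "ols-jitter") -> dict:
    pri = spec.priors
    if init_strategy == "prior":
        a, b = _prior_init(data, spec, rng)
    else:
        a, b = _ols_init(data, spec, rng)
    state: dict = {"a": a, "b": b}
    state["sigma2"] = max(4.0 * math.exp(rng.normal(0, 0.2)), 1e-3)
    state["sigma0_2"] = max(float(np.var(a)) + 1.0, 1e-2)
    state["sigma1_2"] = max(float(np.var(b)) + 1e-6, 1e-8)
    if spec.has_covariate:
        state["p00"] = pri.p0_mean + rng.normal(0, 0.5)
        state["p10"] = pri.p1_mean + rng.normal(0, 0.005)
        state["p01"] = rng.normal(0, 0.1)
        state["p11"] = rng.normal(0, 0.001)
    elif spec.kind == "mixture":
        state["p0"] = pri.p0_mean + rng.normal(0, 0.5)
        q25, q75 = np.percentile(b, [25, 75])
        state["lambda1"] = min(q25, -1e-4)
        state["c"] = max(q75 - q25, 1e-3)
        state["pi1"] = 0.5
        state["sigma_l1_2"] = 1.0
    else:
        state["p0"] = float(np.clip(np.mean(a) + rng.normal(0, 0.5), 1.0, 39.0))
        state["p1"] = min(float(np.mean(b)) + rng.normal(0, 0.002), -1e-6)
    if spec.recall_error == "shared":
        state["delta"] = 0.0
        state["sigma_d_2"] = 100.0
    elif spec.recall_error == "individual":
        state["delta"] = np.zeros(data.n_subjects)
        state["sigma_d_2"] = 100.0
    for k, v in fixed.items():
        if k in ("a", "b", "delta") and np.ndim(v) == 0 and np.ndim(state.get(k, 0)) == 1:
            state[k] = np.full(data.n_subjects, float(v))
        else:
            state[k] = np.asarray(v, dtype=float) if np.ndim(v) else float(v)
    return state


# --- likelihood helpers -----------------------------------------------------

def _obs_ll_vector(spec: ModelSpec, data: CohortArrays, a, b, sigma2, delta):
    t = data.times_with_recall_shift(delta if spec.recall_error != "none" else None)
    mean = a[data.subj] + b[data.subj] * t
    sigma = math.sqrt(sigma2)
    lo, hi = spec.score_bounds
    if spec.likelihood == "t3":
        return trunc_t_logpdf(data.score, mean, sigma, df=spec.likelihood_df,
                              lower=lo, upper=hi)
    return trunc_normal_logpdf(data.score, mean, sigma, lower=lo, upper=hi)


def _a_logprior(spec, state, a, data):
    lo, hi = spec.score_bounds
    s0 = math.sqrt(state["sigma0_2"])
    if spec.has_covariate:
        mean = state["p00"] + state["p01"] * data.covariate
    else:
        mean = state["p0"]
    return trunc_normal_logpdf(a, mean, s0, lower=lo, upper=hi)


def _b_logprior(spec, state, b, data):
    s1 = math.sqrt(state["sigma1_2"])
    if spec.has_covariate:
        mean = state["p10"] + state["p11"] * data.covariate
        return trunc_normal_logpdf(b, mean, s1, upper=0.0)
    if spec.kind == "mixture":
        return mixture_slope_logprior(b, state["lambda1"], state["c"],
                                      state["pi1"], s1)
    return trunc_normal_logpdf(b, state["p1"], s1, upper=0.0)


# --- the sampler ------------------------------------------------------------

class _Chain:
    def __init__(self, spec: ModelSpec, data: CohortArrays,
                 settings: McmcSettings, chain_idx: int, fixed: dict):
        self.spec = spec
        self.data = data
        self.fixed = set(fixed)
        self.rng = np.random.default_rng(
            np.random.SeedSequence(entropy=settings.seed % (2 ** 31),
                                   spawn_key=(chain_idx,)))
        self.state = _init_state(spec, data, self.rng, fixed,
                                 settings.init_strategy)
        n = data.n_subjects
        self.step = {"a": np.full(n, 1.0), "b": np.full(n, 0.02)}
        for name in self._scalar_blocks():
            self.step[name] = 0.1
        if spec.recall_error == "individual":
            self.step["delta"] = np.full(n, 20.0)
        elif spec.recall_error == "shared":
            self.step["delta"] = 20.0
        self.ll = _obs_ll_vector(spec, data, self.state["a"], self.state["b"],
                                 self.state["sigma2"], self.state.get("delta"))
        self.t_adapt = 0

    def _scalar_blocks(self):
        spec = self.spec
        names = ["sigma2", "sigma0_2", "sigma1_2"]
        if spec.has_covariate:
            names += ["p00", "p01", "p10", "p11"]
        elif spec.kind == "mixture":
            names += ["p0", "lambda1", "c", "pi1", "sigma_l1_2"]
        else:
            names += ["p0", "p1"]
        if spec.recall_error != "none":
            names += ["sigma_d_2"]
        return [n for n in names]

    # -- adaptation --
    def _adapt(self, name, acc, idx=None):
        gamma = (self.t_adapt + 10.0) ** -0.6
        if idx is None:
            self.step[name] *= math.exp(gamma * (acc - _ACCEPT_TARGET))
        else:
            self.step[name] *= np.exp(gamma * (acc - _ACCEPT_TARGET))

    # -- vectorised per-subject updates --
    def _update_subject_vec(self, name, adapting):
        if name in self.fixed:
            return
        spec, data, state = self.spec, self.data, self.state
        cur = state[name]
        prop = cur + self.step[name] * self.rng.standard_normal(len(cur))
        if name == "a":
            lo, hi = spec.score_bounds
            ok = (prop >= lo) & (prop <= hi)
            prop_safe = np.clip(prop, lo, hi)
            prior_cur = _a_logprior(spec, state, cur, data)
            prior_prop = np.where(ok, _a_logprior(spec, state, prop_safe, data), -np.inf)
            ll_prop = _obs_ll_vector(spec, data, prop_safe, state["b"],
                                     state["sigma2"], state.get("delta"))
        else:  # b
            ok = prop <= 0.0
            prop_safe = np.minimum(prop, 0.0)
            prior_cur = _b_logprior(spec, state, cur, data)
            prior_prop = np.where(ok, _b_logprior(spec, state, prop_safe, data), -np.inf)
            ll_prop = _obs_ll_vector(spec, data, state["a"], prop_safe,
                                     state["sigma2"], state.get("delta"))
        d_obs = data.segment_sum(ll_prop) - data.segment_sum(self.ll)
        log_ratio = d_obs + prior_prop - prior_cur
        accept = ok & (np.log(self.rng.random(len(cur))) < log_ratio)
        if np.any(accept):
            state[name] = np.where(accept, prop, cur)
            obs_acc = accept[data.subj]
            self.ll = np.where(obs_acc, ll_prop, self.ll)
        if adapting:
            self._adapt(name, accept.astype(float), idx=True)

    # -- scalar hyper updates --
    def _cond_terms(self, name, state):
        """Log-density terms involving a scalar hyperparameter."""
        spec, data = self.spec, self.data
        pri = spec.priors
        t = 0.0
        if name in ("p0", "p00", "p01", "sigma0_2"):
            t += float(np.sum(_a_logprior(spec, state, state["a"], data)))
        if name in ("p1", "p10", "p11", "sigma1_2", "lambda1", "c", "pi1"):
            t += float(np.sum(_b_logprior(spec, state, state["b"], data)))
        if name in ("p0", "p00"):
            t += _norm_logpdf(state[name], pri.p0_mean, pri.p0_sd)
        elif name in ("p1", "p10"):
            t += _norm_logpdf(state[name], pri.p1_mean, pri.p1_sd)
        elif name in ("p01", "p11"):
            t += _norm_logpdf(state[name], 0.0, pri.covariate_coef_sd)
        elif name == "lambda1":
            t += _norm_logpdf(state["lambda1"], 0.0,
                              math.sqrt(state["sigma_l1_2"]))
        elif name == "c":
            t += float(trunc_normal_logpdf(state["c"], 0.0, pri.mixture_sep_sd,
                                           lower=0.0))
        elif name == "pi1":
            w1, w2 = pri.dirichlet_weights
            t += _beta_lp(min(max(state["pi1"], 1e-12), 1 - 1e-12), w1, w2)
        elif name == "sigma_l1_2":
            t += _norm_logpdf(state["lambda1"], 0.0,
                              math.sqrt(state["sigma_l1_2"]))
            t += _invgamma_lp(state["sigma_l1_2"], pri.variance_prior_shape,
                              pri.variance_prior_rate)
        elif name == "sigma_d_2":
            t += float(np.sum(_norm_logpdf(np.atleast_1d(state["delta"]), 0.0,
                                           math.sqrt(state["sigma_d_2"]))))
            t += _invgamma_lp(state["sigma_d_2"], pri.variance_prior_shape,
                              pri.variance_prior_rate)
        if name in ("sigma0_2", "sigma1_2", "sigma2"):
            t += _invgamma_lp(state[name], pri.variance_prior_shape,
                              pri.variance_prior_rate)
        return t

    def _update_scalar(self, name, adapting):
        if name in self.fixed:
            return
        state = self.state
        log_scale = name.startswith("sigma")
        cur = state[name]
        if log_scale:
            prop = cur * math.exp(self.step[name] * self.rng.standard_normal())
            jac = math.log(prop) - math.log(cur)
        else:
            prop = cur + self.step[name] * self.rng.standard_normal()
            jac = 0.0
        if (name == "c" and prop < 0) or (name == "pi1" and not 0 < prop < 1):
            if adapting:
                self._adapt(name, 0.0)
            return
        cur_terms = self._cond_terms(name, state)
        trial = dict(state)
        trial[name] = prop
        if name == "sigma2":
            ll_prop = _obs_ll_vector(self.spec, self.data, state["a"], state["b"],
                                     prop, state.get("delta"))
            prop_terms = float(np.sum(ll_prop)) + self._cond_terms(name, trial)
            cur_terms += float(np.sum(self.ll))
        else:
            prop_terms = self._cond_terms(name, trial)
        log_ratio = prop_terms - cur_terms + jac
        accept = math.log(self.rng.random()) < log_ratio
        if accept:
            state[name] = prop
            if name == "sigma2":
                self.ll = ll_prop
        if adapting:
            self._adapt(name, 1.0 if accept else 0.0)

    def _update_delta(self, adapting):
        if self.spec.recall_error == "none" or "delta" in self.fixed:
            return
        spec, data, state = self.spec, self.data, self.state
        sd = math.sqrt(state["sigma_d_2"])
        if spec.recall_error == "shared":
            cur = state["delta"]
            prop = cur + self.step["delta"] * self.rng.standard_normal()
            ll_prop = _obs_ll_vector(spec, data, state["a"], state["b"],
                                     state["sigma2"], prop)
            log_ratio = (float(np.sum(ll_prop)) - float(np.sum(self.ll))
                         + _norm_logpdf(prop, 0.0, sd)
                         - _norm_logpdf(cur, 0.0, sd))
            accept = math.log(self.rng.random()) < log_ratio
            if accept:
                state["delta"] = prop
                self.ll = ll_prop
            if adapting:
                self._adapt("delta", 1.0 if accept else 0.0)
        else:
            cur = state["delta"]
            prop = cur + self.step["delta"] * self.rng.standard_normal(len(cur))
            ll_prop = _obs_ll_vector(spec, data, state["a"], state["b"],
                                     state["sigma2"], prop)
            d_obs = data.segment_sum(np.where(data.anchor, ll_prop - self.ll, 0.0))
            log_ratio = (d_obs + _norm_logpdf(prop, 0.0, sd)
                         - _norm_logpdf(cur, 0.0, sd))
            accept = np.log(self.rng.random(len(cur))) < log_ratio
            state["delta"] = np.where(accept, prop, cur)
            obs_acc = accept[data.subj] & data.anchor
            self.ll = np.where(obs_acc, ll_prop, self.ll)
            if adapting:
                self._adapt("delta", accept.astype(float), idx=True)

    def sweep(self, adapting: bool):
        self._update_subject_vec("a", adapting)
        self._update_subject_vec("b", adapting)
        for name in self._scalar_blocks():
            self._update_scalar(name, adapting)
        self._update_delta(adapting)
        if adapting:
            self.t_adapt += 1


def fit(spec: ModelSpec, cohort: Cohort, settings: McmcSettings | None = None,
        fixed: dict | None = None) -> PosteriorSamples:
    """Draw from the posterior of a model on a cohort.

    Anchored model kinds anchor the cohort themselves if it is not already
    anchored.  ``fixed`` clamps named parameters at given values (they are
    excluded from updating but still enter the density) -- useful for
    conditional checks and conjugate-limit validation.

    The result is deterministic given ``(spec, cohort, settings, fixed)``.
    """
    settings = settings or McmcSettings()
    fixed = dict(fixed or {})
    if spec.anchored:
        cohort = anchor_cohort(cohort)
    data = CohortArrays(cohort, spec.covariate_name)
    if settings.n_draws < 500:
        warnings.warn("fewer than 500 kept draws per chain; report with caution",
                      stacklevel=2)

    param_names = None
    chains_draws: list[dict[str, np.ndarray]] = []
    lp_all, ll_all = [], []
    for c in range(settings.n_chains):
        ch = _Chain(spec, data, settings, c, fixed)
        for _ in range(settings.n_warmup):
            ch.sweep(adapting=True)
        kept: dict[str, list] = {}
        lp_list, ll_list = [], []
        for it in range(settings.n_draws * settings.thin):
            ch.sweep(adapting=False)
            if (it + 1) % settings.thin:
                continue
            for k, v in ch.state.items():
                kept.setdefault(k, []).append(np.copy(v) if np.ndim(v) else v)
            lp_list.append(joint_log_density(spec, data, ch.state))
            ll_list.append(observation_loglik(spec, data, ch.state))
        chains_draws.append({k: np.asarray(v) for k, v in kept.items()})
        lp_all.append(lp_list)
        ll_all.append(ll_list)
        param_names = list(kept)

    draws = {k: np.stack([cd[k] for cd in chains_draws]) for k in param_names}
    lp = np.asarray(lp_all)
    loglik = np.asarray(ll_all)

    diag, converged = _diagnose(draws)
    if not converged:
        warnings.warn(
            "MCMC convergence warning: at least one parameter has split-R-hat "
            "> 1.05; inspect diagnostics before reporting results.",
            stacklevel=2)
    return PosteriorSamples(spec=spec, settings=settings,
                            subject_ids=list(data.subject_ids), draws=draws,
                            lp=lp, loglik=loglik, cohort=cohort,
                            diagnostics=diag, converged=converged)


def _diagnose(draws: dict[str, np.ndarray]) -> tuple[pd.DataFrame, bool]:
    rows = {}
    for name, d in draws.items():
        rhat = split_rhat(d)
        ess = effective_sample_size(d)
        if d.ndim == 2:
            rows[name] = pd.Series({"rhat": float(rhat), "ess": float(ess)})
        else:
            for j in range(d.shape[2]):
                rows[f"{name}[{j}]"] = pd.Series(
                    {"rhat": float(rhat[j]), "ess": float(ess[j])})
    diag = pd.DataFrame(rows).T
    finite = diag["rhat"].dropna()
    converged = bool((finite <= 1.05).all()) if len(finite) else True
    return diag, converged


def dic(samples: PosteriorSamples, spec: ModelSpec | None = None,
        cohort: Cohort | None = None) -> float:
    """Deviance information criterion, DIC = D-bar + p_D.

    Uses the conditional (observation-level) likelihood with the per-subject
    parameters in focus: D = -2 log L(y | a, b, sigma^2), D-bar the posterior
    mean deviance, and p_D = D-bar - D(posterior means).  Lower is better.
    """
    spec = spec or samples.spec
    data = CohortArrays(cohort if cohort is not None else samples.cohort,
                        spec.covariate_name)
    dbar = float(np.mean(-2.0 * samples.loglik))
    at_mean = {
        "a": samples.stacked("a").mean(axis=0),
        "b": np.minimum(samples.stacked("b").mean(axis=0), 0.0),
        "sigma2": float(samples.stacked("sigma2").mean()),
    }
    if spec.recall_error != "none":
        at_mean["delta"] = samples.stacked("delta").mean(axis=0)
    dhat = -2.0 * observation_loglik(spec, data, at_mean)
    if not np.isfinite(dhat):
        raise ValueError("deviance at the posterior mean is non-finite")
    return dbar + (dbar - dhat)
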