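"""Sampler behaviour: determinism, density consistency, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from alsprog import (
    Cohort,
    McmcSettings,
    ModelSpec,
    SubjectRecord,
    VisitObservation,
    dic,
    fit,
    joint_log_density,
)
from alsprog.inference import effective_sample_size, split_rhat
from alsprog.models import CohortArrays


def test_settings_validation():
    with pytest.raises(ValueError):
        McmcSettings(n_chains=1)
    with pytest.raises(ValueError):
        McmcSettings(n_draws=0)
    with pytest.raises(ValueError):
        McmcSettings(init_strategy="magic")


def test_short_run_warns(small_cohort):
    with pytest.warns(UserWarning, match="fewer than 500"):
        fit(ModelSpec(kind="linear"), small_cohort,
            McmcSettings(n_chains=2, n_warmup=20, n_draws=20, seed=1))


def test_fit_deterministic(small_cohort, fast_settings):
    s1 = fit(ModelSpec(kind="linear"), small_cohort, fast_settings)
    s2 = fit(ModelSpec(kind="linear"), small_cohort, fast_settings)
    for name in s1.draws:
        np.testing.assert_array_equal(s1.draws[name], s2.draws[name])
    np.testing.assert_array_equal(s1.lp, s2.lp)


def test_seed_changes_draws(small_cohort, fast_settings):
    s1 = fit(ModelSpec(kind="linear"), small_cohort, fast_settings)
    s2 = fit(ModelSpec(kind="linear"), small_cohort,
             McmcSettings(n_chains=2, n_warmup=150, n_draws=150, seed=8))
    assert not np.array_equal(s1.draws["p0"], s2.draws["p0"])


def test_stored_lp_matches_recomputed_density(small_cohort, fast_settings):
    spec = ModelSpec(kind="onset_anchored")
    s = fit(spec, small_cohort, fast_settings)
    data = CohortArrays(s.cohort)
    names = list(s.draws)
    for c, d in ((0, 10), (1, 149), (0, 77)):
        params = {k: s.draws[k][c, d] for k in names}
        assert joint_log_density(spec, data, params) == pytest.approx(
            s.lp[c, d], rel=1e-10)


def test_fixed_parameters_stay_clamped(small_cohort, fast_settings):
    s = fit(ModelSpec(kind="linear"), small_cohort, fast_settings,
            fixed={"sigma2": 3.21, "p1": -0.02})
    assert np.all(s.draws["sigma2"] == 3.21)
    assert np.all(s.draws["p1"] == -0.02)
    assert np.std(s.draws["p0"]) > 0  # unclamped parameters still move


def test_empty_history_subject_tracks_hyperprior(fast_settings):
    """A subject with a single visit gets a slope shrunk to the population."""
    visits_rich = tuple(VisitObservation(30.0 * k, 33.0 - 0.9 * k)
                        for k in range(7))
    subs = [SubjectRecord(subject_id=f"R{i}", onset_time_days=-400.0,
                          visits=visits_rich) for i in range(8)]
    subs.append(SubjectRecord(subject_id="LONE", onset_time_days=-400.0,
                              visits=(VisitObservation(0.0, 33.0),)))
    cohort = Cohort(subjects=tuple(subs))
    s = fit(ModelSpec(kind="linear"), cohort, fast_settings)
    j = s.subject_index("LONE")
    b_lone = s.stacked("b")[:, j]
    p1 = s.stacked("p1")
    # the data-free slope cannot stray far from the population mean
    assert abs(b_lone.mean() - p1.mean()) < 3 * p1.std()


def test_mixture_fit_produces_expected_parameters(small_cohort, fast_settings):
    s = fit(ModelSpec(kind="mixture"), small_cohort, fast_settings)
    for name in ("lambda1", "c", "pi1", "sigma_l1_2"):
        assert name in s.draws
    assert np.all(s.stacked("c") >= 0.0)
    assert np.all((s.stacked("pi1") >= 0.0) & (s.stacked("pi1") <= 1.0))


def test_recall_error_shapes(small_cohort, fast_settings):
    shared = fit(ModelSpec(kind="onset_anchored", recall_error="shared"),
                 small_cohort, fast_settings)
    assert shared.draws["delta"].ndim == 2
    indiv = fit(ModelSpec(kind="onset_anchored", recall_error="individual"),
                small_cohort, fast_settings)
    assert indiv.draws["delta"].shape[-1] == len(small_cohort)


def test_summary_and_dataframe(small_cohort, fast_settings):
    s = fit(ModelSpec(kind="linear"), small_cohort, fast_settings)
    summ = s.summary()
    assert {"mean", "sd", "q2.5", "q97.5", "rhat", "ess"} <= set(summ.columns)
    assert "p0" in summ.index
    tidy = s.to_dataframe()
    assert set(tidy.columns) == {"chain", "iteration", "parameter", "value"}
    p0 = tidy[tidy.parameter == "p0"]
    assert len(p0) == fast_settings.n_chains * fast_settings.n_draws


def test_dic_finite_and_orderable(small_cohort, fast_settings):
    s = fit(ModelSpec(kind="linear"), small_cohort, fast_settings)
    val = dic(s)
    assert np.isfinite(val)


# --- diagnostics -------------------------------------------------------------

def test_split_rhat_against_arviz(rng):
    az = pytest.importorskip("arviz")
    d = rng.normal(size=(4, 500)) + np.linspace(0.0, 0.5, 4)[:, None]
    mine = float(split_rhat(d))
    ref = float(az.rhat(az.convert_to_dataset(d)).x)
    assert mine == pytest.approx(ref, abs=0.02)
    # well-mixed chains sit near 1
    good = rng.normal(size=(4, 500))
    assert float(split_rhat(good)) < 1.02


def test_ess_against_arviz(rng):
    az = pytest.importorskip("arviz")
    d = (np.cumsum(rng.normal(size=(4, 500)), axis=1) * 0.05
         + rng.normal(size=(4, 500)))
    mine = float(effective_sample_size(d))
    ref = float(az.ess(az.convert_to_dataset(d)).x)
    assert mine == pytest.approx(ref, rel=0.25)
    iid = rng.normal(size=(4, 500))
    assert float(effective_sample_size(iid)) > 1000


def test_divergent_chains_flagged():
    rng = np.random.default_rng(1)
    d = rng.normal(size=(4, 400)) + np.array([0.0, 0.0, 0.0, 5.0])[:, None]
    assert float(split_rhat(d)) > 1.5


def test_conjugate_posterior_moments():
    """Normal likelihood, unbounded scores, everything fixed except one
    intercept: the posterior is conjugate-normal; check first two moments."""
    vis = tuple(VisitObservation(float(t), 30.0 + e) for t, e in
                zip([0, 30, 60, 90], [1.2, -0.5, 0.8, -1.1]))
    coh = Cohort(subjects=(SubjectRecord(subject_id="A", onset_time_days=-100.0,
                                         visits=vis),))
    spec = ModelSpec(kind="linear", likelihood="normal",
                     score_bounds=(-np.inf, np.inf))
    sigma2, s02, mu0 = 4.0, 25.0, 33.0
    s = fit(spec, coh,
            McmcSettings(n_chains=2, n_warmup=400, n_draws=600, seed=3, thin=5),
            fixed={"b": 0.0, "sigma2": sigma2, "sigma0_2": s02,
                   "sigma1_2": 1e-4, "p0": mu0, "p1": -0.025})
    y = np.array([v.score for v in vis])
    prec = 1.0 / s02 + len(y) / sigma2
    post_mean = (mu0 / s02 + y.sum() / sigma2) / prec
    post_sd = prec ** -0.5
    draws = s.stacked("a")[:, 0]
    assert draws.mean() == pytest.approx(post_mean, abs=4 * post_sd / np.sqrt(len(draws)))
    assert draws.std() == pytest.approx(post_sd, rel=0.15)
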