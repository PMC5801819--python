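"""Model densities: quadrature oracles, closed forms, joint assembly."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from alsprog import (
    Cohort,
    ModelSpec,
    PriorConfig,
    SubjectRecord,
    VisitObservation,
    anchor_cohort,
    joint_log_density,
    trunc_normal_logpdf,
    trunc_t_logpdf,
)
from alsprog.models import (
    CohortArrays,
    _invgamma_logpdf,
    _t3_cdf,
    mixture_class_probabilities,
    mixture_slope_logprior,
    observation_loglik,
)


# --- density oracles ---------------------------------------------------------

@pytest.mark.parametrize("location,scale", [(20.0, 2.0), (5.0, 8.0), (39.0, 1.5)])
def test_trunc_t3_integrates_to_one(location, scale):
    val, _ = integrate.quad(
        lambda y: math.exp(trunc_t_logpdf(y, location, scale, lower=0.0, upper=40.0)),
        0.0, 40.0, limit=200)
    assert abs(val - 1.0) < 1e-8


@pytest.mark.parametrize("mean,sd,lo,hi", [
    (20.0, 3.0, 0.0, 40.0), (-0.025, 0.3, -np.inf, 0.0), (35.0, 10.0, 0.0, 40.0)])
def test_trunc_normal_integrates_to_one(mean, sd, lo, hi):
    a = lo if np.isfinite(lo) else -np.inf
    val, _ = integrate.quad(
        lambda y: math.exp(trunc_normal_logpdf(y, mean, sd, lower=lo, upper=hi)),
        a, hi, limit=200)
    assert abs(val - 1.0) < 1e-8


def test_half_line_trunc_normal_closed_form():
    # truncation of N(0, sd^2) to (-inf, 0] doubles the density: +log 2
    for y in (-3.0, -0.4, -0.01):
        expected = stats.norm.logpdf(y, 0.0, 0.3) + math.log(2.0)
        assert trunc_normal_logpdf(y, 0.0, 0.3, upper=0.0) == pytest.approx(expected)


def test_trunc_t_matches_renormalised_scipy():
    loc, scale, lo, hi = 25.0, 2.5, 0.0, 40.0
    mass = stats.t.cdf((hi - loc) / scale, df=3) - stats.t.cdf((lo - loc) / scale, df=3)
    for y in (1.0, 24.0, 39.5):
        expected = (stats.t.logpdf((y - loc) / scale, df=3)
                    - math.log(scale) - math.log(mass))
        assert trunc_t_logpdf(y, loc, scale, lower=lo, upper=hi) == pytest.approx(
            expected, abs=1e-10)


def test_t3_cdf_matches_scipy():
    z = np.linspace(-6, 6, 41)
    np.testing.assert_allclose(_t3_cdf(z), stats.t.cdf(z, df=3), atol=1e-12)


def test_outside_support_is_minus_inf():
    assert trunc_t_logpdf(41.0, 20.0, 2.0, lower=0.0, upper=40.0) == -np.inf
    assert trunc_normal_logpdf(0.5, 0.0, 1.0, upper=0.0) == -np.inf


def test_invgamma_logpdf_matches_scipy():
    for x in (0.5, 2.0, 10.0):
        expected = stats.invgamma.logpdf(x, 0.001, scale=0.001)
        assert _invgamma_logpdf(x, 0.001, 0.001) == pytest.approx(expected)


# --- mixture prior -----------------------------------------------------------

def test_mixture_collapses_when_separation_zero():
    b = np.array([-0.06, -0.02, -0.005])
    merged = mixture_slope_logprior(b, -0.03, 0.0, 0.3, 0.02)
    single = trunc_normal_logpdf(b, -0.03, 0.02, upper=0.0)
    np.testing.assert_allclose(merged, single, atol=1e-12)


def test_mixture_integrates_to_one():
    val, _ = integrate.quad(
        lambda y: math.exp(float(mixture_slope_logprior(
            np.array([y]), -0.05, 0.04, 0.5, 0.005)[0])),
        -np.inf, 0.0, limit=400)
    assert abs(val - 1.0) < 1e-8


def test_mixture_class_probabilities():
    b = np.array([-0.05, -0.01])
    p_fast = mixture_class_probabilities(b, -0.05, 0.04, 0.5, 0.005)
    assert p_fast[0] > 0.95  # clearly fast
    assert p_fast[1] < 0.05  # clearly slow


# --- model spec --------------------------------------------------------------

def test_model_spec_roundtrip():
    spec = ModelSpec(kind="onset_anchored_covariate", covariate_name="fvc_slope",
                     recall_error="shared", likelihood="normal")
    assert ModelSpec.from_dict(spec.to_dict()) == spec


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(kind="quadratic")
    with pytest.raises(ValueError):
        ModelSpec(kind="linear", recall_error="sometimes")
    with pytest.raises(ValueError):
        ModelSpec(kind="onset_anchored_covariate")  # covariate name required


def test_anchored_flag():
    assert ModelSpec(kind="onset_anchored").anchored
    assert not ModelSpec(kind="linear").anchored


# --- joint density -----------------------------------------------------------

def _one_subject_cohort():
    visits = tuple(VisitObservation(t, s) for t, s in
                   [(0.0, 33.0), (30.0, 32.0), (61.0, 30.5)])
    return Cohort(subjects=(SubjectRecord(
        subject_id="A", onset_time_days=-300.0, visits=visits),))


def test_joint_log_density_hand_assembly():
    cohort = _one_subject_cohort()
    spec = ModelSpec(kind="linear")
    pri = PriorConfig()
    params = dict(a=np.array([33.0]), b=np.array([-0.03]), sigma2=2.0,
                  sigma0_2=9.0, sigma1_2=0.01, p0=32.0, p1=-0.02)
    total = joint_log_density(spec, cohort, params)
    sigma = math.sqrt(params["sigma2"])
    expected = sum(
        trunc_t_logpdf(v.score, 33.0 - 0.03 * v.time_days, sigma,
                       lower=0.0, upper=40.0)
        for v in cohort.subjects[0].visits)
    expected += trunc_normal_logpdf(33.0, 32.0, 3.0, lower=0.0, upper=40.0)
    expected += trunc_normal_logpdf(-0.03, -0.02, 0.1, upper=0.0)
    expected += stats.norm.logpdf(32.0, pri.p0_mean, pri.p0_sd)
    expected += stats.norm.logpdf(-0.02, pri.p1_mean, pri.p1_sd)
    for v in ("sigma2", "sigma0_2", "sigma1_2"):
        expected += stats.invgamma.logpdf(params[v], 0.001, scale=0.001)
    assert total == pytest.approx(expected, rel=1e-12)


def test_joint_log_density_support_violations():
    cohort = _one_subject_cohort()
    spec = ModelSpec(kind="linear")
    good = dict(a=np.array([33.0]), b=np.array([-0.03]), sigma2=2.0,
                sigma0_2=9.0, sigma1_2=0.01, p0=32.0, p1=-0.02)
    assert np.isfinite(joint_log_density(spec, cohort, good))
    for bad in (dict(good, b=np.array([0.5])),
                dict(good, a=np.array([41.0])),
                dict(good, sigma2=-1.0)):
        assert joint_log_density(spec, cohort, bad) == -np.inf


def test_anchored_density_equals_linear_on_anchored_cohort():
    cohort = anchor_cohort(_one_subject_cohort())
    params = dict(a=np.array([33.0]), b=np.array([-0.03]), sigma2=2.0,
                  sigma0_2=9.0, sigma1_2=0.01, p0=32.0, p1=-0.02)
    lp_anchored = joint_log_density(ModelSpec(kind="onset_anchored"), cohort, params)
    lp_linear = joint_log_density(ModelSpec(kind="linear"), cohort, params)
    assert lp_anchored == pytest.approx(lp_linear, rel=1e-14)


def test_anchored_density_requires_anchor():
    with pytest.raises(ValueError, match="anchored"):
        joint_log_density(ModelSpec(kind="onset_anchored"), _one_subject_cohort(),
                          dict(a=np.array([33.0]), b=np.array([-0.03]),
                               sigma2=2.0, sigma0_2=9.0, sigma1_2=0.01,
                               p0=32.0, p1=-0.02))


def test_observation_loglik_per_subject_sums_to_total():
    cohort, spec = _one_subject_cohort(), ModelSpec(kind="linear")
    data = CohortArrays(cohort)
    params = dict(a=np.array([33.0]), b=np.array([-0.03]), sigma2=2.0)
    per = observation_loglik(spec, data, params, per_subject=True)
    total = observation_loglik(spec, data, params)
    assert float(np.sum(per)) == pytest.approx(total)
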