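"""Shared fixtures for the test suite.

MCMC runs in unit tests are deliberately short; the package warns about
short runs and marginal convergence, which is expected here, so those
warnings are silenced suite-wide.
"""

import warnings

import numpy as np
import pytest

from alsprog import (
    Cohort,
    CohortSimConfig,
    McmcSettings,
    SubjectRecord,
    VisitObservation,
    generate_cohort,
)


@pytest.fixture(autouse=True)
def _silence_short_run_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than 500 kept draws")
        warnings.filterwarnings("ignore", message="MCMC convergence warning")
        yield


@pytest.fixture
def fast_settings():
    """Small but deterministic sampler settings for unit tests."""
    return McmcSettings(n_chains=2, n_warmup=150, n_draws=150, seed=7)


@pytest.fixture
def small_cohort():
    """A 30-subject simulated cohort with endpoints, fixed seed."""
    cohort, _ = generate_cohort(CohortSimConfig(n_subjects=30, seed=5))
    return cohort


@pytest.fixture
def tiny_subject():
    """One hand-built subject with four visits and a known onset."""
    visits = tuple(
        VisitObservation(time_days=t, score=s)
        for t, s in [(0.0, 34.0), (28.0, 33.0), (60.0, 31.0), (95.0, 30.0),
                     (180.0, 27.0)]
    )
    return SubjectRecord(subject_id="T1", onset_time_days=-400.0, visits=visits)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
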