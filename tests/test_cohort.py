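"""Domain types, conversion, windowing, anchoring, covariate collapse."""

import math

import numpy as np
import pytest

from alsprog import (
    Cohort,
    SubjectRecord,
    ValidationError,
    VisitObservation,
    add_onset_anchor,
    anchor_cohort,
    collapse_covariate,
    complete_case_subset,
    convert_alsfrsr_to_alsfrs,
    first_score_after,
    normalize_covariates,
    truncate_window,
)
from alsprog.cohort import apply_normalization


# --- ALSFRS-R -> ALSFRS conversion -----------------------------------------

def test_conversion_maximum():
    assert convert_alsfrsr_to_alsfrs((4,) * 10) == 40


def test_conversion_minimum():
    assert convert_alsfrsr_to_alsfrs((0,) * 10) == 0


def test_conversion_hand_sum():
    assert convert_alsfrsr_to_alsfrs((4, 4, 3, 2, 4, 4, 3, 3, 4, 3)) == 34


def test_conversion_out_of_range_names_item():
    with pytest.raises(ValidationError, match="q3_swallowing"):
        convert_alsfrsr_to_alsfrs((4, 4, 5, 2, 4, 4, 3, 3, 4, 3))


def test_conversion_missing_names_item():
    with pytest.raises(ValidationError, match="r1_dyspnea"):
        convert_alsfrsr_to_alsfrs((4, 4, 3, 2, 4, 4, 3, 3, 4, float("nan")))


def test_conversion_wrong_length():
    with pytest.raises(ValidationError, match="10"):
        convert_alsfrsr_to_alsfrs((4, 4, 3))


def test_conversion_in_bounds_and_40_iff_all_four(rng):
    for _ in range(50):
        sub = tuple(rng.integers(0, 5, size=10).tolist())
        total = convert_alsfrsr_to_alsfrs(sub)
        assert 0 <= total <= 40
        assert (total == 40) == all(v == 4 for v in sub)


# --- validation --------------------------------------------------------------

def test_score_out_of_bounds_rejected():
    with pytest.raises(ValidationError, match="outside"):
        VisitObservation(time_days=0.0, score=41.0)
    with pytest.raises(ValidationError, match="outside"):
        VisitObservation(time_days=0.0, score=-0.5)


def test_anchor_must_score_40():
    with pytest.raises(ValidationError, match="maximum score"):
        VisitObservation(time_days=-100.0, score=39.0, is_anchor=True)


def test_positive_onset_rejected():
    with pytest.raises(ValidationError, match="after trial start"):
        SubjectRecord(subject_id="X", onset_time_days=10.0,
                      visits=(VisitObservation(0.0, 30.0),))


def test_onset_after_first_visit_rejected():
    with pytest.raises(ValidationError, match="follows the first observed"):
        SubjectRecord(subject_id="X", onset_time_days=-5.0,
                      visits=(VisitObservation(-10.0, 30.0),))


def test_visits_sorted_on_construction():
    s = SubjectRecord(subject_id="X", onset_time_days=None,
                      visits=(VisitObservation(60.0, 30.0),
                              VisitObservation(0.0, 34.0)))
    assert [v.time_days for v in s.visits] == [0.0, 60.0]


def test_duplicate_subject_ids_rejected():
    v = (VisitObservation(0.0, 30.0),)
    a = SubjectRecord(subject_id="X", onset_time_days=None, visits=v)
    with pytest.raises(ValidationError, match="duplicate"):
        Cohort(subjects=(a, a))


# --- windowing ---------------------------------------------------------------

def test_truncate_window_filters_by_threshold(tiny_subject):
    out = truncate_window(tiny_subject, 91.0)
    assert [v.time_days for v in out.visits] == [0.0, 28.0, 60.0]
    # purity: the input is untouched
    assert len(tiny_subject.visits) == 5


def test_truncate_window_zero_keeps_anchor_and_baseline(tiny_subject):
    anchored = add_onset_anchor(tiny_subject)
    out = truncate_window(anchored, 0.0)
    times = [(v.time_days, v.is_anchor) for v in out.visits]
    assert times == [(-400.0, True), (0.0, False)]


def test_truncate_window_all_after_cutoff_errors():
    s = SubjectRecord(subject_id="X", onset_time_days=None,
                      visits=(VisitObservation(100.0, 30.0),))
    with pytest.raises(ValidationError, match="unusable"):
        truncate_window(s, 91.0)


def test_truncate_window_retains_anchor_for_any_cutoff(tiny_subject):
    anchored = add_onset_anchor(tiny_subject)
    for cutoff in (0.0, 30.0, 91.0, 400.0):
        assert truncate_window(anchored, cutoff).has_anchor


def test_negative_cutoff_rejected(tiny_subject):
    with pytest.raises(ValidationError):
        truncate_window(tiny_subject, -1.0)


# --- endpoint extraction -----------------------------------------------------

def _subj(times, scores=None, anchor_time=None):
    scores = scores or [30.0] * len(times)
    visits = [VisitObservation(t, s) for t, s in zip(times, scores)]
    if anchor_time is not None:
        visits.append(VisitObservation(anchor_time, 40.0, is_anchor=True))
    return SubjectRecord(subject_id="X", onset_time_days=anchor_time,
                         visits=tuple(visits))


def test_first_score_after_exact_day_qualifies():
    s = _subj([0, 180, 365, 390], [34, 30, 26, 25])
    assert first_score_after(s, 365.0) == (365.0, 26.0)


def test_first_score_after_takes_first_qualifying():
    s = _subj([0, 180, 390, 420], [34, 30, 26, 25])
    assert first_score_after(s, 365.0) == (390.0, 26.0)


def test_first_score_after_absent():
    assert first_score_after(_subj([0, 180]), 365.0) is None


def test_first_score_after_ignores_anchors():
    s = SubjectRecord(subject_id="X", onset_time_days=-500.0,
                      visits=(VisitObservation(-500.0, 40.0, is_anchor=True),
                              VisitObservation(0.0, 30.0)))
    assert first_score_after(s, -600.0) == (0.0, 30.0)


def test_first_score_after_monotone(tiny_subject):
    prev_time = -math.inf
    for day in (0.0, 50.0, 100.0, 200.0):
        hit = first_score_after(tiny_subject, day)
        if hit is None:
            continue
        assert hit[0] >= prev_time
        prev_time = hit[0]


# --- anchoring ---------------------------------------------------------------

def test_add_onset_anchor(tiny_subject):
    out = add_onset_anchor(tiny_subject)
    anchors = [v for v in out.visits if v.is_anchor]
    assert len(anchors) == 1
    assert anchors[0].time_days == tiny_subject.onset_time_days
    assert anchors[0].score == 40.0
    assert not tiny_subject.has_anchor  # purity


def test_add_onset_anchor_requires_onset():
    s = _subj([0.0])
    with pytest.raises(ValidationError, match="onset"):
        add_onset_anchor(s)


def test_add_onset_anchor_twice_rejected(tiny_subject):
    with pytest.raises(ValidationError, match="already anchored"):
        add_onset_anchor(add_onset_anchor(tiny_subject))


def test_anchor_cohort_drop_missing(tiny_subject):
    no_onset = _subj([0.0])
    cohort = Cohort(subjects=(tiny_subject, no_onset))
    out = anchor_cohort(cohort, drop_missing_onset=True)
    assert len(out) == 1 and out.subjects[0].has_anchor
    with pytest.raises(ValidationError):
        anchor_cohort(cohort, drop_missing_onset=False)


# --- covariates --------------------------------------------------------------

def test_collapse_covariate_matches_ols():
    series = [(0.0, 1.0), (30.0, 2.0), (60.0, 2.5), (100.0, 4.0)]
    out = collapse_covariate(series, cutoff_days=91.0)
    t = np.array([0.0, 30.0, 60.0])
    x = np.array([1.0, 2.0, 2.5])
    slope, intercept = np.polyfit(t, x, 1)
    assert out.n_points == 3
    assert out.slope == pytest.approx(slope)
    assert out.intercept == pytest.approx(intercept)


def test_collapse_covariate_single_point_missing_slope():
    out = collapse_covariate([(0.0, 3.0)], cutoff_days=91.0)
    assert out.intercept == 3.0
    assert math.isnan(out.slope)


def test_collapse_covariate_empty_errors():
    with pytest.raises(ValidationError):
        collapse_covariate([(100.0, 3.0)], cutoff_days=91.0)


def _cov_cohort():
    subs = []
    for i, x in enumerate([1.0, 2.0, 3.0, float("nan")]):
        subs.append(SubjectRecord(
            subject_id=f"S{i}", onset_time_days=None,
            visits=(VisitObservation(0.0, 30.0),),
            covariates={"weight": x}))
    return Cohort(subjects=tuple(subs), covariate_names=("weight",))


def test_normalize_covariates_training_stats():
    cohort = _cov_cohort()
    normed, table = normalize_covariates(cohort, ["weight"])
    mean, sd = table["weight"]
    assert mean == pytest.approx(2.0)
    assert sd == pytest.approx(1.0)
    vals = [s.covariates["weight"] for s in normed.subjects[:3]]
    assert vals == pytest.approx([-1.0, 0.0, 1.0])
    assert math.isnan(normed.subjects[3].covariates["weight"])
    # reapplying the same table to fresh data uses the stored statistics
    again = apply_normalization(cohort, table)
    assert again.subjects[0].covariates["weight"] == pytest.approx(-1.0)


def test_complete_case_subset():
    cohort = _cov_cohort()
    out = complete_case_subset(cohort, "weight")
    assert [s.subject_id for s in out] == ["S0", "S1", "S2"]
    with pytest.raises(ValidationError, match="unknown covariate"):
        complete_case_subset(cohort, "height")
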