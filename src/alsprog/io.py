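"""Reading and writing cohorts as delimited text.

Three long-format files describe a cohort:

* **visits**: ``subject_id, time_days, alsfrs`` -- or, for revised-scale
  data, the ten sub-score columns ``q1_speech .. q9_climbing_stairs,
  r1_dyspnea`` which are converted to the 0-40 ALSFRS on load.
* **subjects**: ``subject_id, onset_time_days`` plus any scalar covariate
  columns (blank = missing).
* **longitudinal covariates** (optional): ``subject_id, time_days,
  covariate_name, value``; collapsed to OLS intercept/slope covariates with
  :func:`alsprog.cohort.collapse_covariate`.

All readers validate ranges and report the offending row number.
"""

from __future__ import annotations

import math

import pandas as pd

from .cohort import (
    ALSFRSR_ITEMS,
    Cohort,
    SubjectRecord,
    ValidationError,
    VisitObservation,
    collapse_covariate,
    convert_alsfrsr_to_alsfrs,
)

__all__ = ["read_cohort", "write_cohort", "read_visits", "read_subjects",
           "collapse_longitudinal_covariates"]


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype={"subject_id": str})


def read_visits(path) -> dict[str, list[VisitObservation]]:
    """Parse a visits file into per-subject visit lists."""
    df = _read_table(path)
    if "subject_id" not in df or "time_days" not in df:
        raise ValidationError(f"{path}: need subject_id and time_days columns")
    has_total = "alsfrs" in df.columns
    has_sub = all(c in df.columns for c in ALSFRSR_ITEMS)
    if not (has_total or has_sub):
        raise ValidationError(
            f"{path}: need an 'alsfrs' column or the ten revised-scale "
            f"sub-score columns {ALSFRSR_ITEMS}")
    visits: dict[str, list[VisitObservation]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            if has_total and not (isinstance(d["alsfrs"], float) and math.isnan(d["alsfrs"])):
                score = float(d["alsfrs"])
            else:
                score = float(convert_alsfrsr_to_alsfrs([d[c] for c in ALSFRSR_ITEMS]))
            visit = VisitObservation(time_days=float(d["time_days"]), score=score)
        except (ValidationError, ValueError, KeyError) as exc:
            raise ValidationError(f"{path} row {row_no}: {exc}") from exc
        visits.setdefault(str(d["subject_id"]), []).append(visit)
    return visits


def read_subjects(path) -> tuple[dict[str, float | None], dict[str, dict[str, float]], list[str]]:
    """Parse a subjects file: onset times, covariate maps, covariate names."""
    df = _read_table(path)
    if "subject_id" not in df or "onset_time_days" not in df:
        raise ValidationError(f"{path}: need subject_id and onset_time_days columns")
    cov_names = [c for c in df.columns if c not in ("subject_id", "onset_time_days")]
    onsets: dict[str, float | None] = {}
    covs: dict[str, dict[str, float]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        sid = str(d["subject_id"])
        if sid in onsets:
            raise ValidationError(f"{path} row {row_no}: duplicate subject {sid}")
        onset = d["onset_time_days"]
        onset = None if (isinstance(onset, float) and math.isnan(onset)) else float(onset)
        if onset is not None and onset > 0:
            raise ValidationError(
                f"{path} row {row_no}: onset_time_days {onset} must be <= 0")
        onsets[sid] = onset
        covs[sid] = {c: float(d[c]) for c in cov_names}
    return onsets, covs, cov_names


def collapse_longitudinal_covariates(path, cutoff_days: float) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Collapse a long-format covariate file to per-subject intercept/slope.

    Each covariate ``name`` yields two scalar covariates, ``name_intercept``
    and ``name_slope`` (slope missing for single-point series).
    """
    df = _read_table(path)
    need = {"subject_id", "time_days", "covariate_name", "value"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(need)}")
    out: dict[str, dict[str, float]] = {}
    names: set[str] = set()
    for (sid, name), grp in df.groupby(["subject_id", "covariate_name"]):
        series = list(zip(grp["time_days"].astype(float), grp["value"].astype(float)))
        try:
            col = collapse_covariate(series, cutoff_days)
        except ValidationError:
            continue  # nothing inside the window -> both stay missing
        d = out.setdefault(str(sid), {})
        d[f"{name}_intercept"] = col.intercept
        d[f"{name}_slope"] = col.slope
        names.update((f"{name}_intercept", f"{name}_slope"))
    return out, sorted(names)


def read_cohort(visits_path, subjects_path, longitudinal_path=None,
                covariate_cutoff_days: float = 91.0) -> Cohort:
    """Assemble a cohort from the delimited-text files."""
    visits = read_visits(visits_path)
    onsets, covs, cov_names = read_subjects(subjects_path)
    long_names: list[str] = []
    if longitudinal_path is not None:
        long_covs, long_names = collapse_longitudinal_covariates(
            longitudinal_path, covariate_cutoff_days)
        for sid, d in long_covs.items():
            covs.setdefault(sid, {}).update(d)
    missing = set(visits) - set(onsets)
    if missing:
        raise ValidationError(
            f"subjects {sorted(missing)[:5]} appear in visits but not in the "
            "subjects file")
    nan = float("nan")
    all_names = list(cov_names) + long_names
    subjects = []
    for sid in onsets:
        if sid not in visits:
            continue  # subject without any score contributes nothing
        cov = {name: covs.get(sid, {}).get(name, nan) for name in all_names}
        subjects.append(SubjectRecord(
            subject_id=sid, onset_time_days=onsets[sid],
            visits=tuple(sorted(visits[sid], key=lambda v: v.time_days)),
            covariates=cov))
    return Cohort(subjects=tuple(subjects), covariate_names=tuple(all_names))


def write_cohort(cohort: Cohort, visits_path, subjects_path) -> None:
    """Write a cohort back out as the two core CSV files (anchors excluded)."""
    vrows = [
        {"subject_id": s.subject_id, "time_days": v.time_days, "alsfrs": v.score}
        for s in cohort for v in s.observed_visits
    ]
    srows = [
        {"subject_id": s.subject_id, "onset_time_days": s.onset_time_days,
         **{n: s.covariates.get(n, float("nan")) for n in cohort.covariate_names}}
        for s in cohort
    ]
    pd.DataFrame(vrows).to_csv(visits_path, index=False)
    pd.DataFrame(srows).to_csv(subjects_path, index=False)
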