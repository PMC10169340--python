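"""Build the analytic cohort from raw extract tables.

Eligibility (applied in this order, each step logged in the attrition
table): age 40+ as of the patient-characteristics reference year (2015),
at least one index condition (heart failure, COPD or diabetes, from
diagnosis codes during 2016-2019), at least three qualifying primary-care
visit dates during 2018-2019, and no hemodialysis procedure at any point
during 2015-2019 (dialysis patients are seen so frequently and regularly
that temporal regularity is not meaningful for them).

A qualifying visit is any encounter with a family physician lasting at
least five minutes — roughly the mean visit duration, below which an
encounter is more likely a prescription-refill request than a meaningful
clinical contact.  Modality (in person, video, phone, text) is not
restricted.  Multiple qualifying visits on one calendar day collapse to a
single date, since a zero-day interval would make the COV ill-behaved.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import terms
from .codes import CodeList, load_code_lists
from .errors import DataError
from .io import write_table

REFERENCE_YEAR = 2015
STUDY_WINDOW = (pd.Timestamp("2018-01-01"), pd.Timestamp("2019-12-31"))
CONDITION_WINDOW = (pd.Timestamp("2016-01-01"), pd.Timestamp("2019-12-31"))
DATA_SPAN = (pd.Timestamp("2015-01-01"), pd.Timestamp("2019-12-31"))
MIN_VISIT_MINUTES = 5.0
MIN_QUALIFYING_VISITS = 3

_EGFR_RANGE_WINDOWS = [(pd.Timestamp("2018-01-01"), pd.Timestamp("2019-12-31")),
                       (pd.Timestamp("2016-01-01"), pd.Timestamp("2017-12-31"))]
EGFR_MODE = "60+"


def age_group_from_birth_year(birth_year) -> pd.Series:
    """Band ages anchored at the 2015 reference year; under-40 -> NA."""
    by = pd.Series(birth_year)
    bins = [-np.inf, 1925, 1935, 1945, 1955, 1965, 1975]
    labels = ["90+", "80-89", "70-79", "60-69", "50-59", "40-49"]
    return pd.cut(by, bins=bins, labels=labels).astype(object)


def ses_group_from_decile(decile) -> pd.Series:
    d = pd.Series(decile)
    if ((d < 1) | (d > 10)).any():
        raise DataError("SES decile outside 1..10")
    bins = [0, 3, 5, 7, 10]
    labels = ["lowest", "lower", "higher", "highest"]
    return pd.cut(d, bins=bins, labels=labels).astype(object)


def qualify_visits(visits: pd.DataFrame, window=STUDY_WINDOW,
                   min_minutes: float = MIN_VISIT_MINUTES) -> np.ndarray:
    """Qualifying visit dates for one patient, sorted, same-day collapsed."""
    keep = ((visits["provider_role"] == "family_physician")
            & (visits["duration_minutes"] >= min_minutes)
            & (visits["date"] >= window[0]) & (visits["date"] <= window[1]))
    dates = visits.loc[keep, "date"].dt.normalize().drop_duplicates().sort_values()
    return dates.to_numpy(dtype="datetime64[D]")


def _qualifying_dates_all(visits: pd.DataFrame, window, min_minutes) -> pd.DataFrame:
    keep = ((visits["provider_role"] == "family_physician")
            & (visits["duration_minutes"] >= min_minutes)
            & (visits["date"] >= window[0]) & (visits["date"] <= window[1]))
    q = visits.loc[keep, ["patient_id", "date"]].copy()
    q["date"] = q["date"].dt.normalize()
    return q.drop_duplicates().sort_values(["patient_id", "date"]).reset_index(drop=True)


def categorize_egfr_value(value: float) -> str:
    if value >= 60:
        return "60+"
    if value >= 45:
        return "45-59"
    if value >= 30:
        return "30-44"
    return "<30"


def categorize_egfr(labs: pd.DataFrame) -> str:
    """Kidney-function category for one patient.

    Uses the lowest eGFR recorded in 2018-2019; if none, the lowest in
    2016-2017; if still none, imputes the modal category (60+, intact
    kidney function).
    """
    if len(labs) and (labs["egfr"] < 0).any():
        raise DataError("negative eGFR value")
    for lo, hi in _EGFR_RANGE_WINDOWS:
        vals = labs.loc[(labs["date"] >= lo) & (labs["date"] <= hi), "egfr"]
        if len(vals):
            return categorize_egfr_value(float(vals.min()))
    return EGFR_MODE


def _egfr_all(labs: pd.DataFrame, patient_ids: pd.Index) -> pd.Series:
    if len(labs) and (labs["egfr"] < 0).any():
        raise DataError("negative eGFR value")
    cat = pd.Series(EGFR_MODE, index=patient_ids, name="egfr_category")
    # later windows overwrite earlier fallbacks, so iterate fallback-first
    for lo, hi in reversed(_EGFR_RANGE_WINDOWS):
        sel = labs[(labs["date"] >= lo) & (labs["date"] <= hi)]
        if not len(sel):
            continue
        lowest = sel.groupby("patient_id")["egfr"].min()
        lowest = lowest[lowest.index.isin(patient_ids)]
        cat.loc[lowest.index] = [categorize_egfr_value(v) for v in lowest]
    return cat


def flag_condition(records: pd.DataFrame, code_list: CodeList,
                   period=CONDITION_WINDOW) -> bool:
    """True iff >=1 diagnosis record in ``period`` matches the code list."""
    if not len(records):
        return False
    inside = records[(records["date"] >= period[0]) & (records["date"] <= period[1])]
    return any(code_list.matches(c) for c in inside["code"])


def _condition_flags_all(diagnoses: pd.DataFrame, code_lists: dict[str, CodeList],
                         patient_ids: pd.Index, period) -> pd.DataFrame:
    inside = diagnoses[(diagnoses["date"] >= period[0])
                       & (diagnoses["date"] <= period[1])]
    uniq = inside["code"].unique()
    flags = pd.DataFrame(False, index=patient_ids,
                         columns=list(code_lists))
    for name, cl in code_lists.items():
        matching = {c for c in uniq if cl.matches(c)}
        if not matching:
            continue
        hit = inside.loc[inside["code"].isin(matching), "patient_id"].unique()
        flags.loc[flags.index.intersection(hit), name] = True
    return flags


@dataclass
class AnalyticCohort:
    """The analytic cohort: one row per eligible patient plus the qualifying
    visit dates (long table) and the attrition log."""

    patients: pd.DataFrame
    visit_dates: pd.DataFrame
    attrition: pd.DataFrame

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        write_table(self.patients, directory / "cohort.csv")
        write_table(self.visit_dates, directory / "cohort_visit_dates.csv")
        write_table(self.attrition, directory / "attrition.csv")

    @classmethod
    def read(cls, directory: str | Path) -> "AnalyticCohort":
        directory = Path(directory)
        patients = pd.read_csv(directory / "cohort.csv",
                               dtype={"patient_id": str, "clinic_id": str})
        visit_dates = pd.read_csv(directory / "cohort_visit_dates.csv",
                                  dtype={"patient_id": str}, parse_dates=["date"])
        attrition = pd.read_csv(directory / "attrition.csv")
        return cls(patients, visit_dates, attrition)


def _validate_tables(tables: dict[str, pd.DataFrame]) -> None:
    demo = tables["demographics"]
    if demo["patient_id"].duplicated().any():
        dup = demo.loc[demo["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DataError(f"duplicate patient_id in demographics: {dup}")
    if demo["clinic_id"].isna().any() or (demo["clinic_id"] == "").any():
        raise DataError("patient without clinic assignment")
    known = set(demo["patient_id"])
    for name in ("visits", "diagnoses", "labs", "procedures"):
        unknown = set(tables[name]["patient_id"]) - known
        if unknown:
            raise DataError(
                f"{name}: patient_id not in demographics: {sorted(unknown)[:5]}")


def build_cohort(tables: dict[str, pd.DataFrame], *,
                 code_lists: dict[str, CodeList] | None = None,
                 study_window=STUDY_WINDOW, condition_window=CONDITION_WINDOW,
                 data_span=DATA_SPAN, min_visits: int = MIN_QUALIFYING_VISITS,
                 min_minutes: float = MIN_VISIT_MINUTES) -> AnalyticCohort:
    """Apply all eligibility filters and assemble the analytic cohort."""
    _validate_tables(tables)
    code_lists = code_lists or load_code_lists()
    demo = tables["demographics"].set_index("patient_id")

    flags = _condition_flags_all(tables["diagnoses"], code_lists,
                                 demo.index, condition_window)
    qdates = _qualifying_dates_all(tables["visits"], study_window, min_minutes)
    n_qual = qdates.groupby("patient_id").size().reindex(demo.index, fill_value=0)
    proc = tables["procedures"]
    dial = proc[(proc["procedure"].str.lower() == "hemodialysis")
                & (proc["date"] >= data_span[0]) & (proc["date"] <= data_span[1])]
    has_dialysis = demo.index.isin(dial["patient_id"].unique())

    age = REFERENCE_YEAR - demo["birth_year"]
    steps = [
        ("age_under_40", (age >= 40).to_numpy()),
        ("no_index_condition", flags[terms.INDEX_CONDITIONS].any(axis=1).to_numpy()),
        ("under_3_qualifying_visits", (n_qual >= min_visits).to_numpy()),
        ("hemodialysis", ~has_dialysis),
    ]
    keep = np.ones(len(demo), dtype=bool)
    rows = [{"step": "initial", "removed": 0, "remaining": len(demo)}]
    for name, ok in steps:
        removed = int(np.sum(keep & ~ok))
        keep &= ok
        rows.append({"step": name, "removed": removed,
                     "remaining": int(keep.sum())})
    attrition = pd.DataFrame(rows)

    kept = demo.loc[keep]
    patients = pd.DataFrame({
        "patient_id": kept.index,
        "clinic_id": kept["clinic_id"].to_numpy(),
        "age_group": age_group_from_birth_year(kept["birth_year"]).to_numpy(),
        "sex": kept["sex"].to_numpy(),
        "ethnic_group": kept["ethnic_group"].to_numpy(),
        "region": kept["region"].to_numpy(),
        "ses_group": ses_group_from_decile(kept["ses_decile"]).to_numpy(),
        "current_smoker": kept["current_smoker"].astype(bool).to_numpy(),
    })
    patients = patients.join(flags.loc[keep].reset_index(drop=True))
    patients["egfr_category"] = _egfr_all(
        tables["labs"], kept.index).loc[kept.index].to_numpy()
    visit_dates = qdates[qdates["patient_id"].isin(set(kept.index))]
    visit_dates = visit_dates.reset_index(drop=True)

    _assert_invariants(patients, visit_dates, min_visits)
    return AnalyticCohort(patients=patients, visit_dates=visit_dates,
                          attrition=attrition)


def _assert_invariants(patients: pd.DataFrame, visit_dates: pd.DataFrame,
                       min_visits: int) -> None:
    if patients["age_group"].isna().any():
        raise DataError("retained patient without valid age band")
    if len(patients) and not patients[terms.INDEX_CONDITIONS].any(axis=1).all():
        raise DataError("retained patient without index condition")
    counts = visit_dates.groupby("patient_id").size()
    if len(patients) and (counts.reindex(patients["patient_id"]).fillna(0)
                          < min_visits).any():
        raise DataError("retained patient with too few qualifying visits")
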