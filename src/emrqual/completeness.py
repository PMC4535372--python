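"""Core completeness measures.

A *documented visit* (the atom of documented care) is a same-day match
between an office-visit billing and a progress note for the same patient
and physician.  From documented visits follow:

* a physician's *initiation date* — the earliest day with at least 10
  same-day bill/note pairs, taken as the operational start of EMR use;
* *active patients* — rostered patients with at least one documented visit
  in the window under study;
* a patient's *first-EMR date* — their earliest documented visit anywhere;
* per-physician, per-field *completeness rates*: the share of denominator
  patients whose record satisfies the field's measure in the window.

Field measures are at-least-one indicators (a structured blood pressure or
weight, a structured lab result, a prescription, a referral entry, a
consultation letter entry) except visit documentation, where the canonical
per-patient measure requires *all* of the patient's in-window office-visit
billings to carry a same-day note; a per-visit variant (documented visits /
billed visits) is provided alongside.  Cumulative patient profile (CPP)
fields are snapshot booleans evaluated against all rostered patients, with
medical history the union of the past-health and problem-list fields.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .data_model import EMRDataset
from ._dates import DateWindow

__all__ = [
    "EVENT_FIELDS",
    "CPP_FIELDS",
    "ALL_FIELDS",
    "CompletenessRate",
    "match_documented_visits",
    "detect_initiation_date",
    "active_patients",
    "patient_first_emr_date",
    "field_completeness",
    "visit_documentation_per_visit",
]

EVENT_FIELDS = (
    "visit_documentation",
    "blood_pressure",
    "weight",
    "lab_test",
    "prescription",
    "referral",
    "consult_letter",
)

CPP_FIELDS = (
    "cpp_allergies",
    "cpp_immunizations",
    "cpp_active_treatment",
    "cpp_risk_factors",
    "cpp_personal_traits",
    "cpp_family_history",
    "cpp_medical_history",
)

ALL_FIELDS = EVENT_FIELDS + CPP_FIELDS


@dataclass(frozen=True)
class CompletenessRate:
    """One physician x field x window numerator/denominator pair."""

    physician_id: str
    field: str
    window_start: dt.date
    window_end: dt.date
    numerator: int
    denominator: int

    def __post_init__(self):
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(
                f"numerator {self.numerator} outside [0, {self.denominator}]")

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def rate(self) -> float | None:
        """Proportion in [0, 1]; None (never 0) when the denominator is 0."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


def _window_ts(window: DateWindow) -> tuple[pd.Timestamp, pd.Timestamp]:
    start, end = window
    if start >= end:
        raise ValueError(f"malformed window: [{start}, {end})")
    return pd.Timestamp(start), pd.Timestamp(end)


def match_documented_visits(
    billings: pd.DataFrame, notes: pd.DataFrame
) -> pd.DataFrame:
    """Distinct (patient_id, physician_id, date) with an office-visit billing
    AND a progress note on the same day; duplicates collapse."""
    office = billings.loc[
        billings["is_office_visit"],
        ["patient_id", "physician_id", "service_date"],
    ].rename(columns={"service_date": "date"}).drop_duplicates()
    noted = notes[["patient_id", "physician_id", "note_date"]].rename(
        columns={"note_date": "date"}
    ).drop_duplicates()
    out = office.merge(noted, on=["patient_id", "physician_id", "date"])
    return out.sort_values(["physician_id", "patient_id", "date"]).reset_index(
        drop=True
    )


def _require_physician(dataset: EMRDataset, physician_id: str) -> None:
    if physician_id not in set(dataset.physicians["physician_id"]):
        raise KeyError(f"unknown physician_id: {physician_id!r}")


def _daily_pair_counts(dataset: EMRDataset, physician_id: str) -> pd.Series:
    """Matched bill/note pairs per day for one physician.

    Pairs, not distinct patients: a patient with two billed and noted visits
    on one day contributes min(#office bills, #notes) = 2 pairs.
    """
    b = dataset.billings
    b = b[(b["physician_id"] == physician_id) & b["is_office_visit"]]
    n = dataset.notes[dataset.notes["physician_id"] == physician_id]
    if b.empty or n.empty:
        return pd.Series(dtype=int)
    nb = b.groupby(["patient_id", "service_date"]).size()
    nn = n.groupby(["patient_id", "note_date"]).size()
    nb.index.names = nn.index.names = ["patient_id", "date"]
    pairs = pd.concat([nb, nn], axis=1, join="inner").min(axis=1)
    return pairs.groupby(level="date").sum().sort_index()


def detect_initiation_date(
    dataset: EMRDataset,
    physician_id: str,
    min_pairs: int = 10,
    mode: str = "single-day",
) -> dt.date | None:
    """Earliest date at which the physician's EMR shows >= ``min_pairs``
    same-day bill/note pairs.

    ``mode="single-day"`` (default) requires the count on one calendar day
    to reach the threshold; ``mode="cumulative"`` takes the day the running
    total of pairs reaches it.  Returns None when no day qualifies.
    """
    _require_physician(dataset, physician_id)
    daily = _daily_pair_counts(dataset, physician_id)
    if daily.empty:
        return None
    if mode == "single-day":
        hits = daily[daily >= min_pairs]
    elif mode == "cumulative":
        cum = daily.cumsum()
        hits = cum[cum >= min_pairs]
    else:
        raise ValueError(f"unknown initiation mode: {mode!r}")
    if hits.empty:
        return None
    return hits.index[0].date()


def _rostered(dataset: EMRDataset, physician_id: str) -> set[str]:
    r = dataset.rosters
    return set(r.loc[r["physician_id"] == physician_id, "patient_id"])


def active_patients(
    dataset: EMRDataset,
    physician_id: str,
    window: DateWindow,
    visits: pd.DataFrame | None = None,
) -> set[str]:
    """Rostered patients of the physician with >= 1 documented visit with
    that physician dated in the half-open window."""
    _require_physician(dataset, physician_id)
    lo, hi = _window_ts(window)
    if visits is None:
        visits = match_documented_visits(dataset.billings, dataset.notes)
    v = visits[
        (visits["physician_id"] == physician_id)
        & (visits["date"] >= lo)
        & (visits["date"] < hi)
    ]
    return set(v["patient_id"]) & _rostered(dataset, physician_id)


def patient_first_emr_date(
    dataset: EMRDataset,
    patient_id: str,
    visits: pd.DataFrame | None = None,
) -> dt.date | None:
    """Earliest documented visit for the patient with any physician; None if
    the patient never has a same-day bill/note pair."""
    if patient_id not in set(dataset.patients["patient_id"]):
        raise KeyError(f"unknown patient_id: {patient_id!r}")
    if visits is None:
        visits = match_documented_visits(dataset.billings, dataset.notes)
    mine = visits.loc[visits["patient_id"] == patient_id, "date"]
    if mine.empty:
        return None
    return mine.min().date()


def _patients_with_event(
    dataset: EMRDataset, field: str, window: DateWindow
) -> set[str]:
    """Patients with >= 1 qualifying in-window event for an at-least-one field."""
    lo, hi = _window_ts(window)
    if field in ("blood_pressure", "weight"):
        m = dataset.measurements
        sel = m[(m["kind"] == field) & m["structured"]
                & (m["date"] >= lo) & (m["date"] < hi)]
    elif field == "lab_test":
        # only the structured (electronic-feed) labs count; scanned ones do not
        m = dataset.labs
        sel = m[m["structured"] & (m["date"] >= lo) & (m["date"] < hi)]
    elif field == "prescription":
        m = dataset.prescriptions
        sel = m[(m["date"] >= lo) & (m["date"] < hi)]
    elif field == "referral":
        m = dataset.referrals
        sel = m[(m["date"] >= lo) & (m["date"] < hi)]
    elif field == "consult_letter":
        m = dataset.consults
        sel = m[(m["date"] >= lo) & (m["date"] < hi)]
    else:
        raise ValueError(f"not an at-least-one event field: {field!r}")
    return set(sel["patient_id"])


def _cpp_true_patients(dataset: EMRDataset, field: str) -> set[str]:
    col = field.removeprefix("cpp_")
    cpp = dataset.cpp
    if col == "medical_history":
        flag = cpp["past_health"] | cpp["problem_list"]
    else:
        flag = cpp[col]
    return set(cpp.loc[flag.astype(bool), "patient_id"])


def _fully_documented_patients(
    dataset: EMRDataset, physician_id: str, window: DateWindow
) -> set[str]:
    """Patients all of whose in-window office-visit billings with the
    physician carry a same-day note."""
    lo, hi = _window_ts(window)
    b = dataset.billings
    b = b[(b["physician_id"] == physician_id) & b["is_office_visit"]
          & (b["service_date"] >= lo) & (b["service_date"] < hi)]
    bill_days = b[["patient_id", "service_date"]].drop_duplicates().rename(
        columns={"service_date": "date"})
    n = dataset.notes
    n = n[(n["physician_id"] == physician_id)
          & (n["note_date"] >= lo) & (n["note_date"] < hi)]
    note_days = n[["patient_id", "note_date"]].drop_duplicates().rename(
        columns={"note_date": "date"})
    merged = bill_days.merge(note_days, on=["patient_id", "date"],
                             how="left", indicator=True)
    undoc = set(merged.loc[merged["_merge"] == "left_only", "patient_id"])
    return set(bill_days["patient_id"]) - undoc


def field_completeness(
    dataset: EMRDataset,
    physician_id: str,
    field: str,
    window: DateWindow,
    visits: pd.DataFrame | None = None,
    restrict_to: set[str] | None = None,
) -> CompletenessRate:
    """Completeness of one field for one physician over a one-year window.

    Denominator: the physician's active patients in the window for event
    fields; all rostered patients for CPP fields.  ``restrict_to`` further
    intersects the denominator with a patient subset (used for tenure-bin
    strata).  Pass a precomputed ``match_documented_visits`` table via
    ``visits`` to avoid re-matching.
    """
    if field not in ALL_FIELDS:
        raise ValueError(f"unknown field: {field!r}")
    _require_physician(dataset, physician_id)
    start, end = window

    if field in CPP_FIELDS:
        denom = _rostered(dataset, physician_id)
    else:
        denom = active_patients(dataset, physician_id, window, visits=visits)
    if restrict_to is not None:
        denom = denom & restrict_to

    if field in CPP_FIELDS:
        num = denom & _cpp_true_patients(dataset, field)
    else:
        if field == "visit_documentation":
            num = denom & _fully_documented_patients(dataset, physician_id, window)
        else:
            num = denom & _patients_with_event(dataset, field, window)

    return CompletenessRate(
        physician_id=physician_id, field=field,
        window_start=start, window_end=end,
        numerator=len(num), denominator=len(denom),
    )


def visit_documentation_per_visit(
    dataset: EMRDataset, physician_id: str, window: DateWindow
) -> CompletenessRate:
    """Per-visit variant: documented office-visit days / billed office-visit
    days, over the physician's rostered patients in the window."""
    _require_physician(dataset, physician_id)
    lo, hi = _window_ts(window)
    start, end = window
    panel = _rostered(dataset, physician_id)
    b = dataset.billings
    b = b[(b["physician_id"] == physician_id) & b["is_office_visit"]
          & (b["service_date"] >= lo) & (b["service_date"] < hi)
          & b["patient_id"].isin(panel)]
    bill_days = b[["patient_id", "service_date"]].drop_duplicates().rename(
        columns={"service_date": "date"})
    n = dataset.notes
    n = n[(n["physician_id"] == physician_id)
          & (n["note_date"] >= lo) & (n["note_date"] < hi)]
    note_days = n[["patient_id", "note_date"]].drop_duplicates().rename(
        columns={"note_date": "date"})
    documented = bill_days.merge(note_days, on=["patient_id", "date"])
    return CompletenessRate(
        physician_id=physician_id, field="visit_documentation_per_visit",
        window_start=start, window_end=end,
        numerator=len(documented), denominator=len(bill_days),
    )
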