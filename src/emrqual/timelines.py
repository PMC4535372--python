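"""Time-on-EMR stratification and cross-physician aggregation.

Two stratifications drive the completeness summaries:

* **Physician time on EMR** — each physician's record is split into
  anniversary years since their initiation date; a physician contributes to
  year *k* only with a full year of data (the year-*k* window ends on or
  before the extraction date).
* **Patient time on EMR (tenure)** — patients are binned by time from their
  first same-day note/bill pair to the extraction date: <1, 1-2, 2-3 and
  >3 years, evaluated over the final year before extraction.  Event-field
  denominators are confined to active patients; CPP fields use all binned
  rostered patients.

Rates are aggregated with the physician as the unit of analysis: an
unweighted mean across physicians with a normal-approximation 95% CI
(mean +/- 1.96 * sd / sqrt(n), clamped to [0, 1]).  A panel-size-weighted
variant is available behind a flag.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from ._dates import DateWindow, add_years, full_years_between
from .data_model import EMRDataset
from .completeness import (
    ALL_FIELDS,
    CPP_FIELDS,
    CompletenessRate,
    detect_initiation_date,
    field_completeness,
    match_documented_visits,
    visit_documentation_per_visit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TENURE_BIN_LABELS",
    "StratifiedSummary",
    "TimeAnalysisResult",
    "physician_year_window",
    "compute_initiation_dates",
    "eligible_physicians",
    "assign_tenure_bin",
    "aggregate_mean_ci",
    "physician_time_analysis",
    "patient_time_analysis",
]

TENURE_BIN_LABELS = ("<1", "1-2", "2-3", ">3")

_Z95 = 1.96


@dataclass(frozen=True)
class StratifiedSummary:
    """Mean completeness +/- 95% CI across physicians for one field x stratum."""

    field: str
    stratum_type: str  # "physician_year" | "patient_tenure"
    stratum: str
    n_units: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class TimeAnalysisResult:
    """Summaries plus the underlying per-physician rates and exclusion log."""

    summaries: list[StratifiedSummary]
    rates: pd.DataFrame
    exclusions: dict[str, int] = dc_field(default_factory=dict)


def physician_year_window(initiation_date: dt.date, k: int) -> DateWindow:
    """Half-open anniversary window for 1-based year *k* since initiation."""
    if k < 1:
        raise ValueError(f"year index must be >= 1, got {k}")
    return add_years(initiation_date, k - 1), add_years(initiation_date, k)


def compute_initiation_dates(
    dataset: EMRDataset, min_pairs: int = 10, mode: str = "single-day"
) -> dict[str, dt.date | None]:
    """Initiation date per physician (None when undetectable)."""
    return {
        p: detect_initiation_date(dataset, p, min_pairs=min_pairs, mode=mode)
        for p in sorted(dataset.physicians["physician_id"])
    }


def eligible_physicians(
    dataset: EMRDataset,
    k: int,
    initiations: dict[str, dt.date | None] | None = None,
    min_pairs: int = 10,
) -> set[str]:
    """Physicians with a full year of data in year *k*: their year-*k*
    window ends on or before the extraction date."""
    if initiations is None:
        initiations = compute_initiation_dates(dataset, min_pairs=min_pairs)
    ext = dataset.extraction_date
    return {
        p for p, init in initiations.items()
        if init is not None and physician_year_window(init, k)[1] <= ext
    }


def assign_tenure_bin(
    dataset: EMRDataset,
    patient_id: str,
    visits: pd.DataFrame | None = None,
) -> str | None:
    """Tenure bin (<1, 1-2, 2-3, >3 years) from the patient's first
    documented visit to extraction; None without a first-EMR date.

    Bins are half-open in full anniversary years ([0,1), [1,2), [2,3),
    [3,inf)), so a tenure of exactly 3 years falls in ">3".
    """
    from .completeness import patient_first_emr_date

    first = patient_first_emr_date(dataset, patient_id, visits=visits)
    if first is None:
        return None
    years = full_years_between(first, dataset.extraction_date)
    return TENURE_BIN_LABELS[min(years, 3)]


def _tenure_bins(dataset: EMRDataset, visits: pd.DataFrame) -> dict[str, str]:
    """Vectorised tenure-bin assignment for all patients with a first pair."""
    if visits.empty:
        return {}
    firsts = visits.groupby("patient_id")["date"].min()
    ext = dataset.extraction_date
    out: dict[str, str] = {}
    for pat, ts in firsts.items():
        years = full_years_between(ts.date(), ext)
        out[pat] = TENURE_BIN_LABELS[min(years, 3)]
    return out


def aggregate_mean_ci(rates) -> tuple[float, float, float]:
    """Unweighted mean of physician-level rates with a normal 95% CI.

    CI = mean +/- 1.96 * sd / sqrt(n) (sample sd), clamped to [0, 1];
    n = 1 gives a zero-width CI.  Empty input is an error.
    """
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty set of rates")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    half = _Z95 * sd / math.sqrt(arr.size)
    return mean, max(0.0, mean - half), min(1.0, mean + half)


def _weighted_mean_ci(rates, weights) -> tuple[float, float, float]:
    """Panel-size-weighted variant: weighted mean with an effective-n CI."""
    r = np.asarray(list(rates), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if r.size == 0:
        raise ValueError("cannot aggregate an empty set of rates")
    if w.sum() <= 0:
        raise ValueError("weights must be positive")
    mean = float(np.average(r, weights=w))
    if r.size == 1:
        return mean, mean, mean
    var = float(np.average((r - mean) ** 2, weights=w)) * r.size / (r.size - 1)
    n_eff = w.sum() ** 2 / (w ** 2).sum()
    half = _Z95 * math.sqrt(var) / math.sqrt(n_eff)
    return mean, max(0.0, mean - half), min(1.0, mean + half)


def _physician_subset(
    dataset: EMRDataset, physician_id: str, visits: pd.DataFrame
) -> tuple[EMRDataset, pd.DataFrame]:
    """Restrict the dataset to one physician's rostered patients.

    Rate computations only ever touch a physician's own panel, so slicing
    once per physician keeps the per-window filtering cheap.
    """
    panel = set(dataset.rosters.loc[
        dataset.rosters["physician_id"] == physician_id, "patient_id"])
    sub = {}
    for name in dataset.table_names():
        df = dataset.table(name)
        if name == "physicians":
            sub[name] = df[df["physician_id"] == physician_id]
        else:
            sub[name] = df[df["patient_id"].isin(panel)]
    mini = EMRDataset(**sub, extraction_date=dataset.extraction_date)
    return mini, visits[visits["patient_id"].isin(panel)]


def _rates_frame(records: list[tuple[str, str, CompletenessRate]]) -> pd.DataFrame:
    rows = [
        {
            "stratum_type": st, "stratum": s,
            "physician_id": r.physician_id, "field": r.field,
            "window_start": r.window_start.isoformat(),
            "window_end": r.window_end.isoformat(),
            "numerator": r.numerator, "denominator": r.denominator,
            "rate": r.rate,
        }
        for st, s, r in records
    ]
    cols = ["stratum_type", "stratum", "physician_id", "field", "window_start",
            "window_end", "numerator", "denominator", "rate"]
    return pd.DataFrame(rows, columns=cols)


def _summarize(
    records: list[tuple[str, str, CompletenessRate]],
    weighted: bool,
) -> tuple[list[StratifiedSummary], int]:
    """Aggregate defined rates per (stratum, field); count undefined ones."""
    by_key: dict[tuple[str, str, str], list[CompletenessRate]] = {}
    undefined = 0
    for st, s, r in records:
        if not r.defined:
            undefined += 1  # denominator 0: excluded, never imputed as 0
            continue
        by_key.setdefault((st, s, r.field), []).append(r)
    summaries = []
    for (st, s, fld), rs in sorted(by_key.items()):
        vals = [r.rate for r in rs]
        if weighted:
            mean, lo, hi = _weighted_mean_ci(vals, [r.denominator for r in rs])
        else:
            mean, lo, hi = aggregate_mean_ci(vals)
        summaries.append(StratifiedSummary(
            field=fld, stratum_type=st, stratum=s, n_units=len(rs),
            mean=mean, ci_low=lo, ci_high=hi))
    return summaries, undefined


def physician_time_analysis(
    dataset: EMRDataset,
    fields: tuple[str, ...] | list[str] | None = None,
    *,
    min_pairs: int = 10,
    initiation_mode: str = "single-day",
    include_per_visit: bool = True,
    weighted: bool = False,
) -> TimeAnalysisResult:
    """Completeness by physician's duration of EMR use.

    For each year *k* since initiation, each eligible physician's rates are
    computed over their own year-*k* window and aggregated across
    physicians.  Physicians without a detectable initiation date are
    dropped (logged and counted in the exclusions).
    """
    fields = tuple(fields) if fields is not None else ALL_FIELDS
    for f in fields:
        if f not in ALL_FIELDS:
            raise ValueError(f"unknown field: {f!r}")
    visits = match_documented_visits(dataset.billings, dataset.notes)
    initiations = compute_initiation_dates(
        dataset, min_pairs=min_pairs, mode=initiation_mode)
    dropped = sorted(p for p, d in initiations.items() if d is None)
    if dropped:
        logger.info("dropping %d physician(s) without an initiation date: %s",
                    len(dropped), dropped)
    ext = dataset.extraction_date
    detected = {p: d for p, d in initiations.items() if d is not None}

    records: list[tuple[str, str, CompletenessRate]] = []
    max_k = max((full_years_between(d, ext) for d in detected.values()),
                default=0)
    subsets = {
        phys: _physician_subset(dataset, phys, visits) for phys in detected}
    for k in range(1, max_k + 1):
        for phys in sorted(eligible_physicians(dataset, k, initiations=detected)):
            mini, mini_visits = subsets[phys]
            window = physician_year_window(detected[phys], k)
            for fld in fields:
                r = field_completeness(mini, phys, fld, window,
                                       visits=mini_visits)
                records.append(("physician_year", str(k), r))
            if include_per_visit:
                records.append(("physician_year", str(k),
                                visit_documentation_per_visit(mini, phys, window)))

    summaries, undefined = _summarize(records, weighted)
    return TimeAnalysisResult(
        summaries=summaries,
        rates=_rates_frame(records),
        exclusions={
            "physicians_without_initiation": len(dropped),
            "undefined_rates": undefined,
        },
    )


def patient_time_analysis(
    dataset: EMRDataset,
    fields: tuple[str, ...] | list[str] | None = None,
    *,
    weighted: bool = False,
) -> TimeAnalysisResult:
    """Completeness by patient tenure on the EMR.

    Evaluated over the final year before extraction.  Event-field
    denominators are the physician's active patients within each tenure
    bin; CPP fields use all binned rostered patients.  Patients without a
    first-EMR date cannot be binned and are counted as excluded.
    """
    fields = tuple(fields) if fields is not None else ALL_FIELDS
    for f in fields:
        if f not in ALL_FIELDS:
            raise ValueError(f"unknown field: {f!r}")
    visits = match_documented_visits(dataset.billings, dataset.notes)
    ext = dataset.extraction_date
    window = (add_years(ext, -1), ext)
    bins = _tenure_bins(dataset, visits)
    n_unbinned = int((~dataset.patients["patient_id"].isin(bins)).sum())
    if n_unbinned:
        logger.info("%d patient(s) have no first-EMR date and cannot be binned",
                    n_unbinned)

    members_by_label: dict[str, set[str]] = {lab: set() for lab in TENURE_BIN_LABELS}
    for p, b in bins.items():
        members_by_label[b].add(p)

    records: list[tuple[str, str, CompletenessRate]] = []
    for phys in sorted(dataset.physicians["physician_id"]):
        mini, mini_visits = _physician_subset(dataset, phys, visits)
        for label in TENURE_BIN_LABELS:
            members = members_by_label[label]
            if not members:
                continue
            for fld in fields:
                r = field_completeness(mini, phys, fld, window,
                                       visits=mini_visits, restrict_to=members)
                records.append(("patient_tenure", label, r))

    summaries, undefined = _summarize(records, weighted)
    return TimeAnalysisResult(
        summaries=summaries,
        rates=_rates_frame(records),
        exclusions={
            "patients_without_first_emr_date": n_unbinned,
            "undefined_rates": undefined,
        },
    )
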