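"""Dataset container, table schemas, validation, and delimited-text I/O.

An :class:`EMRDataset` holds the flat relational event tables extracted from
a primary-care EMR — physician roster, patient registry, rostering links,
billings, progress notes, structured measurements, labs, prescriptions,
referrals, consultation letters and the cumulative patient profile (CPP)
snapshot — together with the dataset-level extraction date.

On-disk layout: one directory with eleven CSV files (UTF-8, header row,
RFC 4180 quoting, ISO 8601 dates, booleans written ``true``/``false``) plus
``metadata.json`` holding the extraction date.  ``read_dataset`` and
``write_dataset`` are mutual inverses on valid datasets.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EMRDataset",
    "LoadError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "empty_dataset",
    "TABLE_SCHEMAS",
    "CPP_CATEGORIES",
    "MEASUREMENT_KINDS",
]

CPP_CATEGORIES = (
    "allergies",
    "immunizations",
    "active_treatment",
    "risk_factors",
    "personal_traits",
    "family_history",
    "past_health",
    "problem_list",
)

MEASUREMENT_KINDS = ("blood_pressure", "weight")

TABLE_SCHEMAS: dict[str, list[str]] = {
    "physicians": ["physician_id"],
    "patients": ["patient_id", "birth_date", "valid_insurance"],
    "rosters": ["patient_id", "physician_id", "roster_start"],
    "billings": ["patient_id", "physician_id", "service_date", "is_office_visit"],
    "notes": ["patient_id", "physician_id", "note_date"],
    "measurements": ["patient_id", "date", "kind", "structured"],
    "labs": ["patient_id", "date", "structured"],
    "prescriptions": ["patient_id", "physician_id", "date"],
    "referrals": ["patient_id", "date"],
    "consults": ["patient_id", "date"],
    "cpp": ["patient_id", *CPP_CATEGORIES],
}

_DATE_COLS: dict[str, list[str]] = {
    "patients": ["birth_date"],
    "rosters": ["roster_start"],
    "billings": ["service_date"],
    "notes": ["note_date"],
    "measurements": ["date"],
    "labs": ["date"],
    "prescriptions": ["date"],
    "referrals": ["date"],
    "consults": ["date"],
}

_BOOL_COLS: dict[str, list[str]] = {
    "patients": ["valid_insurance"],
    "billings": ["is_office_visit"],
    "measurements": ["structured"],
    "labs": ["structured"],
    "cpp": list(CPP_CATEGORIES),
}

# every table carrying a patient_id foreign key
_PATIENT_FK_TABLES = [
    "rosters", "billings", "notes", "measurements", "labs",
    "prescriptions", "referrals", "consults", "cpp",
]
_PHYSICIAN_FK_TABLES = ["rosters", "billings", "notes", "prescriptions"]


class LoadError(Exception):
    """A dataset directory could not be read (missing file, bad metadata)."""


class ValidationError(Exception):
    """A dataset violates a structural invariant.

    ``problems`` lists row-level diagnostics (table, row index, message).
    """

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "\n  ".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n  ... {len(problems) - 20} more"
        super().__init__(f"{len(problems)} validation problem(s):\n  {preview}{more}")


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_SCHEMAS[name]})
    return _coerce_table(name, df)


def _coerce_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Coerce raw string columns to the schema dtypes (dates, booleans)."""
    df = df.copy()
    for col in _DATE_COLS.get(name, []):
        df[col] = pd.to_datetime(df[col], format="ISO8601", errors="raise")
    for col in _BOOL_COLS.get(name, []):
        if df[col].dtype != bool:
            lowered = df[col].astype(str).str.lower()
            bad = ~lowered.isin(["true", "false"])
            if bad.any():
                rows = list(df.index[bad][:5])
                raise LoadError(
                    f"table {name!r}, column {col!r}: non-boolean values at rows {rows}"
                )
            df[col] = lowered == "true"
    for col in TABLE_SCHEMAS[name]:
        if col.endswith("_id") or col == "kind":
            df[col] = df[col].astype(str) if len(df) else df[col].astype(object)
    return df.reset_index(drop=True)


@dataclass
class EMRDataset:
    """All event tables of one EMR extract plus its extraction date.

    Tables are pandas DataFrames following :data:`TABLE_SCHEMAS`; date
    columns are ``datetime64[ns]`` at day resolution, id columns strings.
    """

    physicians: pd.DataFrame
    patients: pd.DataFrame
    rosters: pd.DataFrame
    billings: pd.DataFrame
    notes: pd.DataFrame
    measurements: pd.DataFrame
    labs: pd.DataFrame
    prescriptions: pd.DataFrame
    referrals: pd.DataFrame
    consults: pd.DataFrame
    cpp: pd.DataFrame
    extraction_date: dt.date
    exclusions: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_SCHEMAS:
            raise KeyError(name)
        return getattr(self, name)

    def table_names(self) -> list[str]:
        return list(TABLE_SCHEMAS)

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any structural invariant fails."""
        problems: list[str] = []
        ext = pd.Timestamp(self.extraction_date)

        for name in TABLE_SCHEMAS:
            df = self.table(name)
            missing = [c for c in TABLE_SCHEMAS[name] if c not in df.columns]
            if missing:
                problems.append(f"{name}: missing columns {missing}")
        if problems:
            raise ValidationError(problems)

        for col, tab in [("patient_id", "patients"), ("physician_id", "physicians")]:
            dup = self.table(tab)[col].duplicated()
            for i in self.table(tab).index[dup]:
                problems.append(f"{tab} row {i}: duplicate {col} "
                                f"{self.table(tab)[col].iloc[i]!r}")

        known_patients = set(self.patients["patient_id"])
        known_physicians = set(self.physicians["physician_id"])
        for name in _PATIENT_FK_TABLES:
            df = self.table(name)
            bad = ~df["patient_id"].isin(known_patients)
            for i in df.index[bad]:
                problems.append(
                    f"{name} row {i}: unknown patient_id {df['patient_id'].iloc[i]!r}")
        for name in _PHYSICIAN_FK_TABLES:
            df = self.table(name)
            bad = ~df["physician_id"].isin(known_physicians)
            for i in df.index[bad]:
                problems.append(
                    f"{name} row {i}: unknown physician_id {df['physician_id'].iloc[i]!r}")

        # one active roster per patient (provincial enrolment is exclusive)
        dup = self.rosters["patient_id"].duplicated()
        for i in self.rosters.index[dup]:
            problems.append(
                f"rosters row {i}: patient {self.rosters['patient_id'].iloc[i]!r} "
                "rostered more than once")

        for name, cols in _DATE_COLS.items():
            df = self.table(name)
            for col in cols:
                late = df[col] > ext
                for i in df.index[late]:
                    problems.append(
                        f"{name} row {i}: {col} {df[col].iloc[i].date()} "
                        f"after extraction date {self.extraction_date}")

        bad_kind = ~self.measurements["kind"].isin(MEASUREMENT_KINDS)
        for i in self.measurements.index[bad_kind]:
            problems.append(
                f"measurements row {i}: unknown kind "
                f"{self.measurements['kind'].iloc[i]!r}")

        if problems:
            raise ValidationError(problems)

    def equals(self, other: "EMRDataset") -> bool:
        """Field-by-field table equality (ignores the exclusions log)."""
        if self.extraction_date != other.extraction_date:
            return False
        return all(self.table(n).equals(other.table(n)) for n in TABLE_SCHEMAS)

    def copy(self) -> "EMRDataset":
        kwargs = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        for n in TABLE_SCHEMAS:
            kwargs[n] = kwargs[n].copy()
        kwargs["exclusions"] = dict(self.exclusions)
        return EMRDataset(**kwargs)


def empty_dataset(extraction_date: dt.date) -> EMRDataset:
    """A valid dataset with empty registries and zero events."""
    return EMRDataset(
        **{name: _empty_table(name) for name in TABLE_SCHEMAS},
        extraction_date=extraction_date,
    )


def read_dataset(directory: str | Path) -> EMRDataset:
    """Load and validate a dataset directory.

    Patients lacking a valid insurance flag or a birth date are excluded at
    load (with their rows in every other table); counts are logged and kept
    in ``dataset.exclusions``.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise LoadError(f"missing metadata file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    try:
        extraction_date = dt.date.fromisoformat(meta["extraction_date"])
    except (KeyError, ValueError) as exc:
        raise LoadError(f"metadata.json: bad or missing extraction_date ({exc})")

    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise LoadError(f"missing table file: {path}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        missing = [c for c in TABLE_SCHEMAS[name] if c not in raw.columns]
        if missing:
            raise LoadError(f"table {name!r}: missing columns {missing}")
        try:
            tables[name] = _coerce_table(name, raw)
        except (ValueError, TypeError) as exc:
            raise ValidationError([f"table {name!r}: unparseable value ({exc})"])

    ds = EMRDataset(**tables, extraction_date=extraction_date)
    _apply_inclusion_criteria(ds)
    ds.validate()
    return ds


def _apply_inclusion_criteria(ds: EMRDataset) -> None:
    """Drop patients without valid insurance or birth date, plus their rows."""
    pats = ds.patients
    bad = (~pats["valid_insurance"].fillna(False).astype(bool)) | pats["birth_date"].isna()
    n_bad = int(bad.sum())
    ds.exclusions["patients_excluded_at_load"] = n_bad
    if n_bad == 0:
        return
    excluded = set(pats.loc[bad, "patient_id"])
    logger.info("excluding %d patient(s) lacking valid insurance or birth date", n_bad)
    ds.patients = pats[~bad].reset_index(drop=True)
    for name in _PATIENT_FK_TABLES:
        df = ds.table(name)
        setattr(ds, name, df[~df["patient_id"].isin(excluded)].reset_index(drop=True))


def write_dataset(dataset: EMRDataset, directory: str | Path) -> None:
    """Write the dataset in the canonical CSV dialect; inverse of read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in TABLE_SCHEMAS:
        df = dataset.table(name)[TABLE_SCHEMAS[name]].copy()
        for col in _DATE_COLS.get(name, []):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
        for col in _BOOL_COLS.get(name, []):
            df[col] = df[col].map({True: "true", False: "false"})
        df.to_csv(directory / f"{name}.csv", index=False)
    (directory / "metadata.json").write_text(
        json.dumps({"extraction_date": dataset.extraction_date.isoformat()}, indent=2)
        + "\n"
    )
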