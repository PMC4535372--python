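import datetime as dt

import pandas as pd
import pytest

from emrqual.data_model import EMRDataset, TABLE_SCHEMAS
from emrqual.simulate import SimulationConfig, generate, _build_table

EXTRACTION = dt.date(2012, 7, 1)


def D(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def build_dataset(
    extraction: dt.date = EXTRACTION,
    physicians=(),
    patients=(),
    rosters=(),
    billings=(),
    notes=(),
    measurements=(),
    labs=(),
    prescriptions=(),
    referrals=(),
    consults=(),
    cpp=(),
    validate: bool = True,
) -> EMRDataset:
    """Assemble a dataset from terse row tuples.

    patients: ids (birth 1970-01-01, valid insurance) or full tuples;
    rosters: (patient, physician) pairs (start 5 years pre-extraction) or
    full tuples; billings default to office visits; cpp rows are
    (patient_id, {category: True, ...}).
    """
    from emrqual.data_model import CPP_CATEGORIES

    def pat_row(p):
        return p if isinstance(p, tuple) else (p, dt.date(1970, 1, 1), True)

    def roster_row(r):
        return r if len(r) == 3 else (*r, dt.date(extraction.year - 5, 1, 1))

    def bill_row(b):
        return b if len(b) == 4 else (*b, True)

    def cpp_row(c):
        pat, flags = c
        return (pat, *[bool(flags.get(cat, False)) for cat in CPP_CATEGORIES])

    tables = {
        "physicians": [(p,) for p in physicians],
        "patients": [pat_row(p) for p in patients],
        "rosters": [roster_row(r) for r in rosters],
        "billings": [bill_row(b) for b in billings],
        "notes": list(notes),
        "measurements": list(measurements),
        "labs": list(labs),
        "prescriptions": list(prescriptions),
        "referrals": list(referrals),
        "consults": list(consults),
        "cpp": [cpp_row(c) for c in cpp],
    }
    ds = EMRDataset(
        **{name: _build_table(name, tables[name]) for name in TABLE_SCHEMAS},
        extraction_date=extraction,
    )
    if validate:
        ds.validate()
    return ds


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_physicians=8, panel_size_mean=25, seed=7)
    return generate(cfg)
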