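"""Brute-force reference implementations used to cross-check the engine.

These work on plain python row tuples with nested loops and no pandas, so
they stay independent of the implementation they verify.
"""

import datetime as dt


def _rows(df, cols):
    return [
        tuple(v.date() if isinstance(v, dt.datetime) else v for v in t)
        for t in df[list(cols)].itertuples(index=False)
    ]


def billing_rows(ds):
    return _rows(ds.billings, ["patient_id", "physician_id", "service_date",
                               "is_office_visit"])


def note_rows(ds):
    return _rows(ds.notes, ["patient_id", "physician_id", "note_date"])


def brute_match(billings, notes):
    """O(n^2) nested-loop same-day matcher over raw row tuples."""
    out = set()
    for (bp, bdoc, bdate, office) in billings:
        if not office:
            continue
        for (np_, ndoc, ndate) in notes:
            if bp == np_ and bdoc == ndoc and bdate == ndate:
                out.add((bp, bdoc, bdate))
    return out


def brute_active(ds, physician_id, window):
    lo, hi = window
    matches = brute_match(billing_rows(ds), note_rows(ds))
    rostered = {
        r.patient_id for r in ds.rosters.itertuples()
        if r.physician_id == physician_id}
    return {
        pat for (pat, doc, d) in matches
        if doc == physician_id and lo <= d < hi and pat in rostered}


def brute_first_emr_date(ds, patient_id):
    matches = brute_match(billing_rows(ds), note_rows(ds))
    dates = [d for (pat, _doc, d) in matches if pat == patient_id]
    return min(dates) if dates else None


def _event_dates(ds, field, patient_id):
    if field == "blood_pressure" or field == "weight":
        return [m.date.date() for m in ds.measurements.itertuples()
                if m.patient_id == patient_id and m.kind == field and m.structured]
    if field == "lab_test":
        return [m.date.date() for m in ds.labs.itertuples()
                if m.patient_id == patient_id and m.structured]
    if field == "prescription":
        return [m.date.date() for m in ds.prescriptions.itertuples()
                if m.patient_id == patient_id]
    if field == "referral":
        return [m.date.date() for m in ds.referrals.itertuples()
                if m.patient_id == patient_id]
    if field == "consult_letter":
        return [m.date.date() for m in ds.consults.itertuples()
                if m.patient_id == patient_id]
    raise ValueError(field)


def brute_field_completeness(ds, physician_id, field, window):
    """(numerator, denominator) by direct per-patient scanning."""
    lo, hi = window
    rostered = {
        r.patient_id for r in ds.rosters.itertuples()
        if r.physician_id == physician_id}
    if field.startswith("cpp_"):
        denom = rostered
        col = field.removeprefix("cpp_")
        num = 0
        flags = {}
        for row in ds.cpp.itertuples():
            if col == "medical_history":
                flags[row.patient_id] = bool(row.past_health or row.problem_list)
            else:
                flags[row.patient_id] = bool(getattr(row, col))
        for pat in denom:
            if flags.get(pat, False):
                num += 1
        return num, len(denom)

    denom = brute_active(ds, physician_id, window)
    num = 0
    for pat in denom:
        if field == "visit_documentation":
            bill_days = {
                b.service_date.date() for b in ds.billings.itertuples()
                if b.patient_id == pat and b.physician_id == physician_id
                and b.is_office_visit and lo <= b.service_date.date() < hi}
            note_days = {
                n.note_date.date() for n in ds.notes.itertuples()
                if n.patient_id == pat and n.physician_id == physician_id
                and lo <= n.note_date.date() < hi}
            ok = bill_days <= note_days
        else:
            ok = any(lo <= d < hi for d in _event_dates(ds, field, pat))
        if ok:
            num += 1
    return num, len(denom)


def random_fixture(rng, n_events=200, n_patients=12, n_physicians=3,
                   extraction=dt.date(2012, 7, 1)):
    """A small random but valid dataset for oracle-equivalence checks."""
    from conftest import build_dataset

    phys = [f"d{i}" for i in range(n_physicians)]
    pats = [f"p{i}" for i in range(n_patients)]
    roster_of = {p: phys[int(rng.integers(n_physicians))] for p in pats}
    rosters = [(p, roster_of[p]) for p in pats]
    day0 = extraction - dt.timedelta(days=730)

    def rand_date():
        # coarse 10-day grid so independent bills and notes still collide
        return day0 + dt.timedelta(days=10 * int(rng.integers(0, 73)))

    billings, notes, measurements, labs, rx, refs, cons = [], [], [], [], [], [], []
    for _ in range(n_events):
        pat = pats[int(rng.integers(n_patients))]
        # mostly the roster physician, sometimes another one
        doc = roster_of[pat] if rng.random() < 0.7 else \
            phys[int(rng.integers(n_physicians))]
        d = rand_date()
        kind = int(rng.integers(7))
        if kind == 0:
            billings.append((pat, doc, d, bool(rng.random() < 0.8)))
            if rng.random() < 0.5:  # same-day note, as documented care produces
                notes.append((pat, doc, d))
        elif kind == 1:
            notes.append((pat, doc, d))
        elif kind == 2:
            measurements.append(
                (pat, d, ["blood_pressure", "weight"][int(rng.integers(2))],
                 bool(rng.random() < 0.7)))
        elif kind == 3:
            labs.append((pat, d, bool(rng.random() < 0.7)))
        elif kind == 4:
            rx.append((pat, doc, d))
        elif kind == 5:
            refs.append((pat, d))
        else:
            cons.append((pat, d))
    cpp = [(p, {c: bool(rng.random() < 0.5)
                for c in ("allergies", "immunizations", "active_treatment",
                          "risk_factors", "personal_traits", "family_history",
                          "past_health", "problem_list")}) for p in pats]
    return build_dataset(
        extraction=extraction, physicians=phys, patients=pats, rosters=rosters,
        billings=billings, notes=notes, measurements=measurements, labs=labs,
        prescriptions=rx, referrals=refs, consults=cons, cpp=cpp)
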