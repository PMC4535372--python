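import datetime as dt

import numpy as np
import pytest

from emrqual.completeness import (
    CompletenessRate,
    active_patients,
    detect_initiation_date,
    field_completeness,
    match_documented_visits,
    patient_first_emr_date,
    visit_documentation_per_visit,
)

from conftest import D, EXTRACTION, build_dataset
from oracles import (
    billing_rows,
    brute_field_completeness,
    brute_match,
    note_rows,
    random_fixture,
)

WIN = (D("2012-01-01"), D("2012-07-01"))
YEAR = (D("2011-07-01"), D("2012-07-01"))


def visits_as_set(visits):
    return {(r.patient_id, r.physician_id, r.date.date())
            for r in visits.itertuples()}


class TestMatchDocumentedVisits:
    def test_same_day_pair_matches(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p1"], rosters=[("p1", "d0")],
            billings=[("p1", "d0", D("2012-03-01"), True)],
            notes=[("p1", "d0", D("2012-03-01"))],
        )
        got = visits_as_set(match_documented_visits(ds.billings, ds.notes))
        assert got == {("p1", "d0", D("2012-03-01"))}

    def test_next_day_note_does_not_match(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p1"], rosters=[("p1", "d0")],
            billings=[("p1", "d0", D("2012-03-01"), True)],
            notes=[("p1", "d0", D("2012-03-02"))],
        )
        assert len(match_documented_visits(ds.billings, ds.notes)) == 0

    def test_non_office_billing_does_not_match(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p1"], rosters=[("p1", "d0")],
            billings=[("p1", "d0", D("2012-03-01"), False)],
            notes=[("p1", "d0", D("2012-03-01"))],
        )
        assert len(match_documented_visits(ds.billings, ds.notes)) == 0

    def test_duplicates_collapse(self):
        d = D("2012-03-01")
        ds = build_dataset(
            physicians=["d0"], patients=["p1"], rosters=[("p1", "d0")],
            billings=[("p1", "d0", d, True)] * 3,
            notes=[("p1", "d0", d)] * 2,
        )
        assert len(match_documented_visits(ds.billings, ds.notes)) == 1

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(2024)
        ds = random_fixture(rng, n_events=200)
        got = visits_as_set(match_documented_visits(ds.billings, ds.notes))
        assert got == brute_match(billing_rows(ds), note_rows(ds))


class TestInitiationDate:
    def _dataset(self, pairs_by_day):
        billings, notes = [], []
        pats = set()
        for day, pairs in pairs_by_day.items():
            for i in range(pairs):
                pat = f"p{i}"
                pats.add(pat)
                billings.append((pat, "d0", day, True))
                notes.append((pat, "d0", day))
        return build_dataset(
            physicians=["d0"], patients=sorted(pats),
            rosters=[(p, "d0") for p in sorted(pats)],
            billings=billings, notes=notes,
        )

    def test_first_day_reaching_ten_pairs_wins(self):
        a, b = D("2010-05-01"), D("2010-06-01")
        ds = self._dataset({a: 9, b: 10})
        assert detect_initiation_date(ds, "d0") == b

    def test_no_notes_means_no_initiation(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p0"], rosters=[("p0", "d0")],
            billings=[("p0", "d0", D("2012-01-01"), True)],
        )
        assert detect_initiation_date(ds, "d0") is None

    def test_pairs_counted_not_distinct_patients(self):
        # one patient, 10 bill/note pairs on one day
        d = D("2011-02-03")
        ds = build_dataset(
            physicians=["d0"], patients=["p0"], rosters=[("p0", "d0")],
            billings=[("p0", "d0", d, True)] * 10,
            notes=[("p0", "d0", d)] * 10,
        )
        assert detect_initiation_date(ds, "d0") == d

    def test_cumulative_mode_sums_across_days(self):
        days = [D("2010-01-01") + dt.timedelta(days=i) for i in range(5)]
        ds = self._dataset({d: 2 for d in days})
        assert detect_initiation_date(ds, "d0") is None
        assert detect_initiation_date(ds, "d0", mode="cumulative") == days[4]

    def test_threshold_configurable(self):
        ds = self._dataset({D("2010-05-01"): 4})
        assert detect_initiation_date(ds, "d0", min_pairs=4) == D("2010-05-01")

    def test_unknown_physician_raises(self):
        ds = build_dataset(physicians=["d0"])
        with pytest.raises(KeyError):
            detect_initiation_date(ds, "dX")

    def test_recovers_ground_truth_on_simulation(self, small_cohort):
        ds, gt = small_cohort
        for phys, init in gt.initiation_dates.items():
            assert detect_initiation_date(ds, phys) == init


class TestActivePatients:
    def _ds(self):
        return build_dataset(
            physicians=["d0"], patients=["p0", "p1", "p2"],
            rosters=[("p0", "d0"), ("p1", "d0"), ("p2", "d0")],
            billings=[
                ("p0", "d0", WIN[0], True),            # on window start
                ("p1", "d0", D("2011-06-01"), True),   # before window
                ("p2", "d0", D("2012-06-30"), True),   # inside
            ],
            notes=[
                ("p0", "d0", WIN[0]),
                ("p1", "d0", D("2011-06-01")),
                ("p2", "d0", D("2012-06-30")),
            ],
        )

    def test_window_start_included_prior_visit_excluded(self):
        assert active_patients(self._ds(), "d0", WIN) == {"p0", "p2"}

    def test_window_end_excluded(self):
        assert active_patients(self._ds(), "d0", (D("2011-01-01"), WIN[0])) == {"p1"}

    def test_unrostered_patient_never_active(self):
        ds = build_dataset(
            physicians=["d0", "d1"], patients=["p0"], rosters=[("p0", "d1")],
            billings=[("p0", "d0", D("2012-02-01"), True)],
            notes=[("p0", "d0", D("2012-02-01"))],
        )
        assert active_patients(ds, "d0", WIN) == set()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        from oracles import brute_active
        for _ in range(5):
            ds = random_fixture(rng, n_events=150)
            for phys in ds.physicians["physician_id"]:
                assert active_patients(ds, phys, YEAR) == brute_active(ds, phys, YEAR)


class TestFirstEmrDate:
    def test_minimum_over_visits(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p0"], rosters=[("p0", "d0")],
            billings=[("p0", "d0", D("2010-03-03"), True),
                      ("p0", "d0", D("2010-03-07"), True)],
            notes=[("p0", "d0", D("2010-03-03")),
                   ("p0", "d0", D("2010-03-07"))],
        )
        assert patient_first_emr_date(ds, "p0") == D("2010-03-03")

    def test_bills_without_same_day_note_give_none(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p0"], rosters=[("p0", "d0")],
            billings=[("p0", "d0", D("2010-03-03"), True)],
            notes=[("p0", "d0", D("2010-03-04"))],
        )
        assert patient_first_emr_date(ds, "p0") is None

    def test_unknown_patient_raises(self):
        ds = build_dataset(physicians=["d0"])
        with pytest.raises(KeyError):
            patient_first_emr_date(ds, "pX")


class TestFieldCompleteness:
    def test_prescription_direct_count(self):
        pats = [f"p{i}" for i in range(10)]
        billings = [(p, "d0", D("2012-02-01"), True) for p in pats]
        notes = [(p, "d0", D("2012-02-01")) for p in pats]
        rx = [(p, "d0", D("2012-03-01")) for p in pats[:7]]
        ds = build_dataset(
            physicians=["d0"], patients=pats, rosters=[(p, "d0") for p in pats],
            billings=billings, notes=notes, prescriptions=rx,
        )
        r = field_completeness(ds, "d0", "prescription", WIN)
        assert (r.numerator, r.denominator, r.rate) == (7, 10, 0.7)

    def test_cpp_medical_history_merges_past_health_and_problem_list(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p0", "p1"],
            rosters=[("p0", "d0"), ("p1", "d0")],
            cpp=[("p0", {"past_health": False, "problem_list": True}),
                 ("p1", {})],
        )
        r = field_completeness(ds, "d0", "cpp_medical_history", WIN)
        assert (r.numerator, r.denominator) == (1, 2)

    def test_cpp_denominator_is_all_rostered_not_active(self):
        # p1 has no visit at all but is rostered: counts for CPP
        ds = build_dataset(
            physicians=["d0"], patients=["p0", "p1"],
            rosters=[("p0", "d0"), ("p1", "d0")],
            billings=[("p0", "d0", D("2012-02-01"), True)],
            notes=[("p0", "d0", D("2012-02-01"))],
            cpp=[("p0", {"allergies": True}), ("p1", {"allergies": True})],
        )
        r = field_completeness(ds, "d0", "cpp_allergies", WIN)
        assert (r.numerator, r.denominator) == (2, 2)
        r = field_completeness(ds, "d0", "prescription", WIN)
        assert r.denominator == 1

    def test_scanned_labs_do_not_count(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p0"], rosters=[("p0", "d0")],
            billings=[("p0", "d0", D("2012-02-01"), True)],
            notes=[("p0", "d0", D("2012-02-01"))],
            labs=[("p0", D("2012-02-02"), False)],
        )
        r = field_completeness(ds, "d0", "lab_test", WIN)
        assert (r.numerator, r.denominator) == (0, 1)

    def test_visit_documentation_per_patient_requires_all_visits_noted(self):
        ds = build_dataset(
            physicians=["d0"], patients=["p0"], rosters=[("p0", "d0")],
            billings=[("p0", "d0", D("2012-02-01"), True),
                      ("p0", "d0", D("2012-03-01"), True)],
            notes=[("p0", "d0", D("2012-02-01"))],
        )
        r = field_completeness(ds, "d0", "visit_documentation", WIN)
        assert (r.numerator, r.denominator) == (0, 1)
        v = visit_documentation_per_visit(ds, "d0", WIN)
        assert (v.numerator, v.denominator) == (1, 2)

    def test_undefined_rate_flagged_never_zero(self):
        ds = build_dataset(physicians=["d0"])
        r = field_completeness(ds, "d0", "prescription", WIN)
        assert not r.defined
        assert r.rate is None

    def test_rate_invariant_under_duplicated_event_rows(self):
        rng = np.random.default_rng(77)
        ds = random_fixture(rng, n_events=200)
        import pandas as pd

        dup = ds.copy()
        for name in ("billings", "notes", "prescriptions", "labs"):
            t = dup.table(name)
            setattr(dup, name, pd.concat([t, t], ignore_index=True))
        for phys in ds.physicians["physician_id"]:
            for fld in ("visit_documentation", "prescription", "lab_test"):
                a = field_completeness(ds, phys, fld, YEAR)
                b = field_completeness(dup, phys, fld, YEAR)
                assert (a.numerator, a.denominator) == (b.numerator, b.denominator)

    def test_adding_qualifying_event_never_decreases_rate(self):
        rng = np.random.default_rng(3)
        ds = random_fixture(rng, n_events=150)
        import pandas as pd

        phys = ds.physicians["physician_id"].iloc[0]
        before = field_completeness(ds, phys, "referral", YEAR)
        denom = active_patients(ds, phys, YEAR)
        assert denom, "fixture must yield active patients"
        pat = sorted(denom)[0]
        extra = pd.DataFrame({"patient_id": [pat],
                              "date": [pd.Timestamp("2012-01-15")]})
        ds.referrals = pd.concat([ds.referrals, extra], ignore_index=True)
        after = field_completeness(ds, phys, "referral", YEAR)
        assert after.rate >= before.rate
        assert after.denominator == before.denominator

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            ds = random_fixture(rng, n_events=180)
            for phys in ds.physicians["physician_id"]:
                for fld in ("visit_documentation", "blood_pressure", "weight",
                            "lab_test", "prescription", "referral",
                            "consult_letter", "cpp_allergies",
                            "cpp_medical_history"):
                    got = field_completeness(ds, phys, fld, YEAR)
                    want = brute_field_completeness(ds, phys, fld, YEAR)
                    assert (got.numerator, got.denominator) == want

    def test_rejects_malformed_window_and_unknown_field(self):
        ds = build_dataset(physicians=["d0"])
        with pytest.raises(ValueError):
            field_completeness(ds, "d0", "prescription", (WIN[1], WIN[0]))
        with pytest.raises(ValueError):
            field_completeness(ds, "d0", "not_a_field", WIN)


def test_completeness_rate_invariants():
    with pytest.raises(ValueError):
        CompletenessRate("d0", "prescription", WIN[0], WIN[1], 5, 3)
    r = CompletenessRate("d0", "prescription", WIN[0], WIN[1], 3, 4)
    assert r.rate == pytest.approx(0.75)
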