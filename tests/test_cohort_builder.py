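from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from herbsurv.codes import load_codeset, load_neuro_codesets
from herbsurv.cohort_builder import (
    assign_exposure,
    build_cohort,
    categorize_cause,
    classify_neuro,
    compute_cci,
    cumulative_chm_days,
    cumulative_ddd,
    diagnosis_onset,
)
from herbsurv.errors import DataError
from herbsurv.synthetic_claims import ClaimsBundle

HIV = load_codeset("hiv")


def ev(rows):
    return pd.DataFrame(rows, columns=["date", "setting", "code"])


class TestDiagnosisOnset:
    def test_three_outpatient_within_year(self):
        events = ev([
            (date(2012, 1, 1), "outpatient", "042"),
            (date(2012, 4, 10), "outpatient", "043.1"),
            (date(2012, 10, 27), "outpatient", "044"),
        ])
        assert diagnosis_onset(events, HIV) == date(2012, 1, 1)

    def test_two_outpatient_insufficient(self):
        events = ev([
            (date(2012, 1, 1), "outpatient", "042"),
            (date(2012, 4, 10), "outpatient", "042"),
        ])
        assert diagnosis_onset(events, HIV) is None

    def test_single_inpatient_qualifies(self):
        events = ev([(date(2014, 6, 1), "inpatient", "043")])
        assert diagnosis_onset(events, HIV) == date(2014, 6, 1)

    def test_outpatient_visits_spread_beyond_window(self):
        events = ev([
            (date(2012, 1, 1), "outpatient", "042"),
            (date(2013, 4, 10), "outpatient", "042"),
            (date(2013, 6, 1), "outpatient", "042"),
            (date(2013, 9, 1), "outpatient", "042"),
        ])
        # the window starting at the second visit holds three visits
        assert diagnosis_onset(events, HIV) == date(2013, 4, 10)

    def test_agrees_with_exhaustive_window_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = 10
            days = np.sort(rng.integers(0, 900, size=n))
            settings = rng.choice(["inpatient", "outpatient"], size=n,
                                  p=[0.15, 0.85])
            events = ev([
                (date(2011, 1, 1) + timedelta(days=int(d)), s, "042")
                for d, s in zip(days, settings)
            ])
            got = diagnosis_onset(events, HIV)
            # oracle: check every matched event date as a window start
            expected = None
            dts = [date(2011, 1, 1) + timedelta(days=int(d)) for d in days]
            for i, d0 in enumerate(dts):
                win = [j for j in range(n)
                       if d0 <= dts[j] < d0 + timedelta(days=365)]
                n_in = sum(settings[j] == "inpatient" for j in win)
                n_out = sum(settings[j] == "outpatient" for j in win)
                if n_in >= 1 or n_out >= 3:
                    expected = d0
                    break
            assert got == expected

    def test_monotone_in_added_events(self):
        base = ev([
            (date(2012, 5, 1), "outpatient", "042"),
            (date(2012, 6, 1), "outpatient", "042"),
            (date(2012, 7, 1), "outpatient", "042"),
        ])
        onset0 = diagnosis_onset(base, HIV)
        more = pd.concat([base, ev([(date(2012, 1, 1), "inpatient", "042")])])
        assert diagnosis_onset(more, HIV) <= onset0


class TestClassifyNeuro:
    def test_cns_infection_stream(self):
        events = ev([
            (date(2013, 2, 1), "outpatient", "320.9"),
            (date(2013, 2, 8), "outpatient", "320.9"),
            (date(2013, 2, 15), "outpatient", "320.9"),
        ])
        onset, subtypes = classify_neuro(events, date(2012, 1, 1))
        assert onset == date(2013, 2, 1)
        assert subtypes == {"cns_infection"}

    def test_peripheral_neuropathy_stream(self):
        events = ev([
            (date(2013, 2, 1), "outpatient", "357.0"),
            (date(2013, 2, 8), "outpatient", "357.0"),
            (date(2013, 2, 15), "outpatient", "357.0"),
        ])
        _, subtypes = classify_neuro(events, date(2012, 1, 1))
        assert subtypes == {"peripheral_neuropathy"}

    def test_events_before_reference_ignored(self):
        events = ev([
            (date(2010, 2, 1), "outpatient", "320.9"),
            (date(2010, 2, 8), "outpatient", "320.9"),
            (date(2010, 2, 15), "outpatient", "320.9"),
        ])
        onset, subtypes = classify_neuro(events, date(2012, 1, 1))
        assert onset is None and subtypes == set()


def rx(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "date", "class", "product_code",
                 "product_kind", "days", "daily_dose_g", "ddd_amount"],
    )


class TestExposure:
    def test_two_sevens_reach_threshold(self):
        rows = rx([
            ("P1", date(2015, 3, 3), "CHM", "HQ", "single_herb", 7, 1.0, np.nan),
            ("P1", date(2015, 3, 10), "CHM", "HQ", "single_herb", 7, 1.0, np.nan),
        ])
        assert cumulative_chm_days(rows, date(2015, 3, 1)) == 14
        status, idx = assign_exposure(rows, date(2015, 3, 1))
        assert status == "chm_user"
        assert idx == date(2015, 3, 11)  # day after the crossing prescription

    def test_thirteen_days_is_excluded_not_nonuser(self):
        rows = rx([
            ("P1", date(2015, 3, 3), "CHM", "HQ", "single_herb", 13, 1.0, np.nan),
        ])
        assert cumulative_chm_days(rows, date(2015, 3, 1)) == 13
        status, idx = assign_exposure(rows, date(2015, 3, 1))
        assert status == "exclude_low_chm" and idx is None

    def test_no_chm_is_nonuser(self):
        status, idx = assign_exposure(rx([]), date(2015, 3, 1))
        assert status == "non_user" and idx is None

    def test_empty_stream_zero_days(self):
        assert cumulative_chm_days(rx([]), date(2015, 3, 1)) == 0

    def test_negative_days_rejected(self):
        rows = rx([
            ("P1", date(2015, 3, 3), "CHM", "HQ", "single_herb", -1, 1.0, np.nan),
        ])
        with pytest.raises(DataError):
            cumulative_chm_days(rows, date(2015, 3, 1))


class TestCci:
    def test_no_prior_diagnoses(self):
        assert compute_cci(ev([]), date(2012, 1, 1)) == (0.0, "0")

    def test_single_diabetes_code(self):
        events = ev([(date(2010, 5, 1), "outpatient", "250.01")])
        score, group = compute_cci(events, date(2012, 1, 1))
        assert score >= 1 and group == "1-2"

    def test_four_distinct_categories(self):
        events = ev([
            (date(2010, 5, 1), "outpatient", "250.0"),
            (date(2010, 6, 1), "outpatient", "428.0"),
            (date(2010, 7, 1), "outpatient", "571.5"),
            (date(2010, 8, 1), "outpatient", "585"),
        ])
        score, group = compute_cci(events, date(2012, 1, 1))
        assert group == ">=3"
        assert score == 1 + 1 + 1 + 2

    def test_hierarchy_counts_severe_only(self):
        events = ev([
            (date(2010, 5, 1), "outpatient", "153.0"),   # malignancy
            (date(2010, 6, 1), "outpatient", "197.0"),   # metastatic
        ])
        score, group = compute_cci(events, date(2012, 1, 1))
        assert score == 6 and group == "1-2"

    def test_diagnoses_on_or_after_reference_ignored(self):
        events = ev([(date(2012, 1, 1), "outpatient", "250.0")])
        assert compute_cci(events, date(2012, 1, 1)) == (0.0, "0")


class TestDdd:
    def test_no_art_rows(self):
        out = cumulative_ddd(rx([]), date(2012, 1, 1), date(2013, 1, 1))
        assert out["total"] == 0.0

    def test_rows_outside_range(self):
        rows = rx([
            ("P1", date(2014, 3, 3), "NRTI", "ART-NRTI", "art", 30, np.nan, 30.0),
        ])
        out = cumulative_ddd(rows, date(2012, 1, 1), date(2013, 1, 1))
        assert out["NRTI"] == 0.0

    def test_three_nrti_rows(self):
        rows = rx([
            ("P1", date(2012, 3, 1), "NRTI", "ART-NRTI", "art", 30, np.nan, 30.0),
            ("P1", date(2012, 5, 1), "NRTI", "ART-NRTI", "art", 30, np.nan, 30.0),
            ("P1", date(2012, 7, 1), "NRTI", "ART-NRTI", "art", 30, np.nan, 30.0),
        ])
        out = cumulative_ddd(rows, date(2012, 1, 1), date(2013, 1, 1))
        assert out["NRTI"] == 90.0 and out["total"] == 90.0


@pytest.mark.parametrize(
    "code,version,expected",
    [
        ("A41.9", 10, "infections_parasites"),
        ("I21.0", 10, "circulatory"),
        ("800", 9, "other"),
        ("garbage", 10, "other"),
    ],
)
def test_categorize_cause(code, version, expected):
    assert categorize_cause(code, version) == expected


# ---------------------------------------------------------------------------
# Cohort assembly


def _micro_bundle():
    """Two HIV/neuro patients: a clean user and a 13-day low-CHM case."""
    patients = pd.DataFrame({
        "id": ["U1", "L1"],
        "sex": ["M", "M"],
        "birth_date": pd.to_datetime(["1985-01-01", "1985-01-01"]),
    })
    dx_rows = []
    for pid in ("U1", "L1"):
        for off in (0, 3, 6):
            dx_rows.append((pid, date(2012, 1, 5) + timedelta(days=off),
                            "outpatient", 9, "042"))
        for off in (0, 3, 6):
            dx_rows.append((pid, date(2013, 1, 5) + timedelta(days=off),
                            "outpatient", 9, "320.9"))
    diagnoses = pd.DataFrame(
        dx_rows, columns=["patient_id", "date", "setting", "icd_version", "code"])
    diagnoses["date"] = pd.to_datetime(diagnoses["date"])
    rx_rows = [
        ("U1", date(2013, 2, 1), "CHM", "HQ", "single_herb", 7, 1.0, np.nan),
        ("U1", date(2013, 2, 10), "CHM", "HQ", "single_herb", 7, 1.0, np.nan),
        ("L1", date(2013, 2, 1), "CHM", "HQ", "single_herb", 13, 1.0, np.nan),
    ]
    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "date", "class", "product_code",
                          "product_kind", "days", "daily_dose_g", "ddd_amount"])
    prescriptions["date"] = pd.to_datetime(prescriptions["date"])
    deaths = pd.DataFrame(columns=["patient_id", "date", "cause_code",
                                   "icd_version"])
    deaths["date"] = pd.to_datetime(deaths["date"])
    return ClaimsBundle(patients, diagnoses, prescriptions, deaths, {})


def test_micro_bundle_low_chm_excluded():
    cohort, tally = build_cohort(_micro_bundle())
    assert tally["low_chm"] == 1
    assert tally["malignancy"] == 0  # no malignancy codes anywhere
    assert list(cohort["patient_id"]) == ["U1"]
    row = cohort.iloc[0]
    assert row["chm_user"] == 1
    assert row["index_date"] == date(2013, 2, 11)
    assert row["index_duration_days"] == 366  # 2012 is a leap year
    assert row["neuro_subtypes"] == "cns_infection"


def test_planted_tallies_match_exactly(small_bundle, small_cohort):
    cohort, tally = small_cohort
    planted = small_bundle.provenance["planted"]
    for bin_ in ("neuro_before_hiv", "missing_demographics", "low_chm",
                 "malignancy"):
        assert tally[bin_] == planted[bin_], bin_
    assert tally["died_before_index"] == 0
    assert len(cohort) == planted["retained"]


def test_cohort_rows_are_internally_consistent(small_cohort):
    cohort, _ = small_cohort
    assert (cohort["followup_days"] > 0).all()
    assert ((cohort["event"] == 0) == (cohort["cause_category"] == "none")).all()
    assert (cohort["index_duration_days"] >= 0).all()
    assert set(cohort["age_band"]) <= {"lt30", "30to40", "ge40"}
    users = cohort.loc[cohort["chm_user"] == 1]
    assert ((users["index_date"] > users["neuro_date"])).all()


def test_cohort_agrees_with_generator_truth(small_bundle, small_cohort):
    cohort, _ = small_cohort
    truth = small_bundle.truth.set_index("patient_id")
    m = cohort.set_index("patient_id").join(truth, rsuffix="_t")
    assert (m["chm_user"] == m["chm_user_t"].astype(int)).all()
    assert (m["age_band"] == m["age_band_t"]).all()
    assert (m["cci_group"] == m["cci_group_t"]).all()
    assert (m["index_date"] == m["index_date_t"]).all()
    died = m["death_date"].notna()
    assert (m["event"].astype(bool) == died).all()
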