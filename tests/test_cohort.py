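from datetime import date

import pandas as pd
import pytest

from amiclaims.cohort import (
    QueryPeriod,
    StudyConfig,
    build_cohort,
    continuously_enrolled,
    era_valid,
    merge_spans,
    version_attribution,
)
from amiclaims.model import ClaimsBundle
from oracles import naive_cohort


def d(s):
    return date.fromisoformat(s)


class TestMergeSpans:
    @pytest.mark.parametrize(
        "spans, expected",
        [
            ([(d("2016-01-01"), d("2016-06-30")), (d("2016-07-01"), d("2016-12-31"))],
             [(d("2016-01-01"), d("2016-12-31"))]),
            ([(d("2016-01-01"), d("2016-03-01")), (d("2016-02-01"), d("2016-04-01"))],
             [(d("2016-01-01"), d("2016-04-01"))]),
            ([], []),
            ([(d("2016-01-01"), d("2016-03-01")), (d("2016-03-10"), d("2016-04-01"))],
             [(d("2016-01-01"), d("2016-03-01")), (d("2016-03-10"), d("2016-04-01"))]),
        ],
    )
    def test_merge(self, spans, expected):
        assert merge_spans(spans) == expected


class TestContinuousEnrollment:
    def test_full_year(self):
        assert continuously_enrolled([(d("2016-01-01"), d("2016-12-31"))], 2016)

    def test_missing_last_day(self):
        assert not continuously_enrolled([(d("2016-01-01"), d("2016-12-30"))], 2016)

    def test_interior_gap_with_allowance(self):
        spans = [(d("2016-01-01"), d("2016-07-03")), (d("2016-07-05"), d("2016-12-31"))]
        assert not continuously_enrolled(spans, 2016, gap_days=0)
        assert continuously_enrolled(spans, 2016, gap_days=1)

    def test_multi_year_span_covers_each_year(self):
        spans = [(d("2014-01-01"), d("2017-12-31"))]
        for y in (2014, 2015, 2016, 2017):
            assert continuously_enrolled(spans, y)


class TestEraGate:
    @pytest.mark.parametrize(
        "version, day, expected",
        [
            ("icd9cm", "2015-09-30", True),
            ("icd9cm", "2015-11-15", False),
            ("icd10cm", "2015-10-01", True),
            ("icd10cm", "2015-09-30", False),
        ],
    )
    def test_boundary(self, version, day, expected):
        assert era_valid(version, d(day), StudyConfig()) is expected


def _hand_bundle():
    """Three persons: a two-claim adult, an infant, and an eligible
    non-case."""
    persons = pd.DataFrame({
        "person_id": ["A", "BABY", "C"],
        "birth_year": [1950, 2016, 1980],
        "gender": ["male", "female", "female"],
    })
    enrollment = pd.DataFrame({
        "person_id": ["A", "BABY", "C"],
        "start_date": pd.to_datetime(["2014-01-01"] * 3),
        "end_date": pd.to_datetime(["2017-12-31"] * 3),
        "plan": ["commercial"] * 3,
    })
    diagnoses = pd.DataFrame({
        "person_id": ["A", "A", "BABY"],
        "service_date": pd.to_datetime(["2016-03-01", "2016-05-01", "2016-06-01"]),
        "code": ["I214", "I213", "I214"],
        "version": ["icd10cm"] * 3,
        "position": ["secondary", "principal", "principal"],
        "setting": ["emergency_department", "inpatient", "inpatient"],
    })
    return ClaimsBundle(persons=persons, enrollment=enrollment, diagnoses=diagnoses)


class TestBuildCohort:
    def test_first_event_any_setting(self, codelist):
        c = build_cohort(_hand_bundle(), codelist, QueryPeriod.year(2016), "any_healthcare")
        row = c.events.set_index("person_id").loc["A"]
        assert str(row["index_date"].date()) == "2016-03-01"
        assert row["setting"] == "emergency_department"
        assert row["age_at_index"] == 66

    def test_inpatient_scope_picks_later_claim(self, codelist):
        c = build_cohort(_hand_bundle(), codelist, QueryPeriod.year(2016), "inpatient")
        row = c.events.set_index("person_id").loc["A"]
        assert str(row["index_date"].date()) == "2016-05-01"

    def test_infant_excluded_from_numerator_and_denominator(self, codelist):
        c = build_cohort(_hand_bundle(), codelist, QueryPeriod.year(2016), "any_healthcare")
        assert "BABY" not in set(c.events["person_id"])
        assert c.denominator == 2  # A and C

    def test_same_day_tie_prefers_inpatient_then_principal(self, codelist):
        b = _hand_bundle()
        b.diagnoses = pd.DataFrame({
            "person_id": ["A", "A", "A"],
            "service_date": pd.to_datetime(["2016-03-01"] * 3),
            "code": ["I219", "I214", "I213"],
            "version": ["icd10cm"] * 3,
            "position": ["principal", "secondary", "principal"],
            "setting": ["emergency_department", "inpatient", "inpatient"],
        })
        c = build_cohort(b, codelist, QueryPeriod.year(2016), "any_healthcare")
        row = c.events.set_index("person_id").loc["A"]
        assert (row["setting"], row["code"]) == ("inpatient", "I213")

    def test_empty_codelist_rejected(self, codelist):
        from amiclaims.codes import CodeList

        with pytest.raises(ValueError, match="empty"):
            build_cohort(_hand_bundle(), CodeList("empty", ()), QueryPeriod.year(2016))

    def test_claim_outside_enrolled_year_cannot_index(self, codelist):
        b = _hand_bundle()
        b.enrollment.loc[0, "end_date"] = pd.Timestamp("2016-12-30")  # person A loses Dec 31
        c = build_cohort(b, codelist, QueryPeriod.year(2016), "any_healthcare")
        assert "A" not in set(c.events["person_id"])


class TestAgainstOracle:
    @pytest.mark.parametrize("scope", ["any_healthcare", "inpatient"])
    @pytest.mark.parametrize("period", [QueryPeriod.years(2014, 2017), QueryPeriod.year(2015)])
    def test_equals_naive_scan(self, midi_bundle, codelist, scope, period):
        from amiclaims.cohort import ANY_HEALTHCARE, INPATIENT_ONLY

        scope_set = ANY_HEALTHCARE if scope == "any_healthcare" else INPATIENT_ONLY
        expected, expected_denom = naive_cohort(midi_bundle, codelist, period, scope_set)
        c = build_cohort(midi_bundle, codelist, period, scope)
        assert c.denominator == expected_denom
        assert set(c.events["person_id"]) == set(expected)
        indexed = c.events.set_index("person_id")
        for pid, key in expected.items():
            row = indexed.loc[pid]
            assert row["index_date"].date() == key[0]
            assert row["code"] == key[3]
            assert row["setting"] == key[5]

    def test_determinism_under_row_shuffle(self, midi_bundle, codelist):
        shuffled = midi_bundle.copy()
        shuffled.diagnoses = shuffled.diagnoses.sample(frac=1, random_state=5).reset_index(drop=True)
        shuffled.enrollment = shuffled.enrollment.sample(frac=1, random_state=6).reset_index(drop=True)
        a = build_cohort(midi_bundle, codelist, QueryPeriod.years(2014, 2017))
        b = build_cohort(shuffled, codelist, QueryPeriod.years(2014, 2017))
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_scope_and_period_monotonicity(self, midi_bundle, codelist):
        full = build_cohort(midi_bundle, codelist, QueryPeriod.years(2014, 2017))
        inpat = build_cohort(midi_bundle, codelist, QueryPeriod.years(2014, 2017), "inpatient")
        year = build_cohort(midi_bundle, codelist, QueryPeriod.year(2016))
        assert set(inpat.events["person_id"]) <= set(full.events["person_id"])
        assert set(year.events["person_id"]) <= set(full.events["person_id"])

    def test_era_partition(self, midi_bundle, codelist):
        c = build_cohort(midi_bundle, codelist, QueryPeriod.years(2014, 2017))
        boundary = pd.Timestamp("2015-10-01")
        ev = c.events
        nine = ev[ev["version"] == "icd9cm"]
        ten = ev[ev["version"] == "icd10cm"]
        assert (pd.to_datetime(nine["index_date"]) < boundary).all()
        assert (pd.to_datetime(ten["index_date"]) >= boundary).all()


class TestVersionAttribution:
    def test_both_requires_one_claim_per_era(self, codelist):
        b = _hand_bundle()
        b.diagnoses = pd.DataFrame({
            "person_id": ["A", "A", "C"],
            "service_date": pd.to_datetime(["2015-06-01", "2015-11-01", "2015-06-01"]),
            "code": ["41071", "I214", "41090"],
            "version": ["icd9cm", "icd10cm", "icd9cm"],
            "position": ["principal"] * 3,
            "setting": ["inpatient"] * 3,
        })
        att = version_attribution(b, codelist, QueryPeriod.year(2015))
        assert att == {"icd9_only": 1, "icd10_only": 0, "both": 1, "total": 2}

    def test_inclusion_exclusion_identity(self, midi_bundle, codelist):
        period = QueryPeriod.year(2015)
        att = version_attribution(midi_bundle, codelist, period)
        union = build_cohort(midi_bundle, codelist, period)
        c9 = build_cohort(midi_bundle, codelist, period, version="icd9cm")
        c10 = build_cohort(midi_bundle, codelist, period, version="icd10cm")
        assert att["total"] == union.size
        assert union.size == c9.size + c10.size - att["both"]
        assert att["icd9_only"] + att["both"] == c9.size
        assert att["icd10_only"] + att["both"] == c10.size
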