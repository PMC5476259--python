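"""Record parsing, the standardisation chain, and murmuration selection."""

import pytest
from hypothesis import given, settings, strategies as st

from murmuration.records import (
    DEFAULT_RULES,
    MurmurationRecord,
    clean_records,
    parse_records,
    select_murmurations,
)

HEADER = (
    "record_id,survey_year,day_index,report_lag_days,latitude,longitude,is_uk,"
    "settlement_class,habitat,flock_size,duration_min,end_seen,ending,"
    "temperature_c,is_garden_feeding,complete,predator_harrier\n"
)


class TestParse:
    def test_empty_file_with_header(self):
        records, issues = parse_records(HEADER)
        assert records == [] and issues == []

    def test_missing_mandatory_column_is_config_error(self):
        with pytest.raises(ValueError, match="flock_size"):
            parse_records("record_id,survey_year,day_index,duration_min,end_seen\n")

    def test_malformed_rows_become_issues_not_aborts(self):
        rows = (
            "a,2,10,today,,,true,,,800,15,true,roost_en_masse,5,false,true,flying\n"
            "b,2,11,today,,,true,,,many,10,true,dispersed,4,false,true,absent\n"  # bad size
            "c,1,12,3,54.0,-2.0,true,rural,reedbed,900,12,false,unknown,,false,true,\n"
            "d,2,13,today,,,true,,,700,8,true,other,3,false,true,engaging\n"
        )
        records, issues = parse_records(HEADER + rows)
        assert len(records) == 3
        assert len(issues) == 1
        assert issues[0].row == 2
        assert "flock_size" in issues[0].reason

    def test_predator_columns_and_schema_mapping(self):
        text = (
            "id,survey_year,day_index,birds,duration_min,end_seen,predator_harrier\n"
            "x,2,30,600,12,true,engaging\n"
        )
        records, issues = parse_records(
            text, schema={"record_id": "id", "flock_size": "birds"}
        )
        assert not issues
        assert records[0].flock_size == 600
        assert records[0].activity_of("harrier") == "engaging"
        assert records[0].activity_of("kestrel") == "absent"

    def test_invariant_violations_rejected(self, make_record):
        with pytest.raises(ValueError):
            make_record(day_index=180)
        with pytest.raises(ValueError):
            make_record(ending="roost_en_masse", end_seen=False)
        with pytest.raises(ValueError):
            make_record(latitude=95.0)


class TestCleanChain:
    def test_empty_input(self):
        survivors, report = clean_records([])
        assert survivors == []
        assert report.input_count == report.output_count == 0
        assert all(v == 0 for v in report.removed.values())

    def test_zero_duration_removed_under_its_rule(self, make_record):
        rec = make_record(duration_min=0.0)
        survivors, report = clean_records([rec])
        assert survivors == []
        assert report.removed["zero_duration"] == 1
        assert report.removal_reason[rec.record_id] == "zero_duration"

    def test_one_defect_of_each_kind_and_five_clean(self, make_record):
        dirty = [
            make_record(report_lag_days="over_month"),
            make_record(complete=False),
            make_record(flock_size=0),
            make_record(duration_min=0.0),
            make_record(is_garden_feeding=True),
        ]
        clean = [make_record() for _ in range(5)]
        survivors, report = clean_records(dirty + clean)
        assert len(survivors) == 5
        assert list(report.removed.values()) == [1, 1, 1, 1, 1]
        assert report.output_count == report.input_count - sum(report.removed.values())

    def test_first_match_attribution_for_multiply_defective(self, make_record):
        rec = make_record(complete=False, duration_min=0.0)
        _, report = clean_records([rec])
        assert report.removal_reason[rec.record_id] == "incomplete"
        assert report.removed["zero_duration"] == 0

    def test_year1_historical_uses_lag_days(self, make_record):
        kept = make_record(survey_year=1, report_lag_days=31)
        dropped = make_record(survey_year=1, report_lag_days=32)
        survivors, report = clean_records([kept, dropped])
        assert survivors == [kept]
        assert report.removed["historical"] == 1

    def test_idempotent(self, make_record):
        records = [make_record(duration_min=0.0)] + [make_record() for _ in range(4)]
        once, _ = clean_records(records)
        twice, second_report = clean_records(once)
        assert twice == once
        assert all(v == 0 for v in second_report.removed.values())

    def test_partition_of_input_ids(self, make_record):
        records = [make_record(flock_size=0), make_record(), make_record(complete=False)]
        survivors, report = clean_records(records)
        survivor_ids = {r.record_id for r in survivors}
        removed_ids = set(report.removal_reason)
        assert survivor_ids | removed_ids == {r.record_id for r in records}
        assert survivor_ids & removed_ids == set()


class TestSelect:
    def test_500_bird_threshold_boundary(self, make_record):
        at = make_record(flock_size=500)
        below = make_record(flock_size=499)
        assert select_murmurations([at, below]) == [at]

    def test_identity_when_all_qualify(self, make_record):
        records = [make_record(flock_size=600 + i) for i in range(4)]
        assert select_murmurations(records, require_end_seen=True,
                                   require_roost_descent=True, uk_only=True) == records

    def test_negative_min_size_rejected(self, make_record):
        with pytest.raises(ValueError):
            select_murmurations([make_record()], min_size=-1)

    @pytest.mark.parametrize(
        "kwargs,expected_ids",
        [
            ({}, {"big_roost", "big_dispersed", "big_unseen", "big_foreign"}),
            ({"require_end_seen": True}, {"big_roost", "big_dispersed", "big_foreign"}),
            ({"require_roost_descent": True}, {"big_roost", "big_foreign"}),
            ({"uk_only": True, "require_roost_descent": True}, {"big_roost"}),
        ],
    )
    def test_filter_truth_table(self, make_record, kwargs, expected_ids):
        records = [
            make_record(record_id="big_roost", flock_size=800),
            make_record(record_id="big_dispersed", flock_size=800, ending="dispersed"),
            make_record(record_id="big_unseen", flock_size=800, end_seen=False,
                        ending="unknown"),
            make_record(record_id="big_foreign", flock_size=800, is_uk=False),
            make_record(record_id="small", flock_size=100),
        ]
        out = select_murmurations(records, **kwargs)
        assert {r.record_id for r in out} == expected_ids

    @given(min_sizes=st.lists(st.integers(0, 5000), min_size=2, max_size=2),
           sizes=st.lists(st.integers(0, 5000), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_survivor_count_monotone_in_min_size(self, min_sizes, sizes):
        records = [
            MurmurationRecord(record_id=str(i), survey_year=2, day_index=10,
                              report_lag_days="today", flock_size=s, duration_min=5.0,
                              end_seen=True, ending="roost_en_masse")
            for i, s in enumerate(sizes)
        ]
        lo, hi = sorted(min_sizes)
        assert len(select_murmurations(records, min_size=hi)) <= len(
            select_murmurations(records, min_size=lo)
        )
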