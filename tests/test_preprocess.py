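"""Edition merging, code truncation, chapter filtering, timeline building."""

import pytest
from hypothesis import given, strategies as st

from trajmine.errors import CodingError, ConfigurationError
from trajmine.preprocess import (
    MergePolicy,
    build_timelines,
    filter_nondisease,
    merge_editions,
    nondisease_category,
    principal_diagnosis,
    round_to_three_digit,
)

from conftest import make_record


class TestMergeEditions:
    def test_alive_in_old_edition_dropped(self, toy_records):
        merged = merge_editions(toy_records, MergePolicy("2010"))
        pids = {r.patient_id for r in merged}
        assert "pA" not in pids  # alive, 2009 only
        assert "pB" in pids  # deceased in 2009 → backfilled
        assert "pC" in pids  # latest edition, kept unconditionally

    def test_single_edition_identity(self):
        records = [make_record("p1", "2010", 0), make_record("p2", "2010", 5)]
        assert merge_editions(records, MergePolicy("2010")) == records

    def test_unknown_latest_edition(self, toy_records):
        with pytest.raises(ConfigurationError, match="2020"):
            merge_editions(toy_records, MergePolicy("2020"))

    def test_merged_patient_set_is_union(self, toy_records):
        merged = merge_editions(toy_records, MergePolicy("2010"))
        latest = {r.patient_id for r in toy_records if r.edition_id == "2010"}
        deceased_old = {
            r.patient_id
            for r in toy_records
            if r.edition_id != "2010" and r.died_in_hospital
        }
        assert {r.patient_id for r in merged} == latest | deceased_old


class TestRounding:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("728.88", "728"),  # rhabdomyolysis sub-code → muscle-disorder chapter
            ("295", "295"),
            ("295.3", "295"),
            ("V58.11", "V58"),
            ("V30", "V30"),
            ("E880.2", "E880"),
            ("E849", "E849"),
            ("038", "038"),
        ],
    )
    def test_examples(self, code, expected):
        assert round_to_three_digit(code) == expected

    @pytest.mark.parametrize("bad", ["", "29", "2953", "V5", "E88", "X12", "295.888"])
    def test_invalid_codes_raise(self, bad):
        with pytest.raises(CodingError):
            round_to_three_digit(bad)

    @given(
        st.one_of(
            st.integers(1, 999).map(lambda n: f"{n:03d}"),
            st.integers(0, 99).map(lambda n: f"V{n:02d}"),
            st.integers(800, 999).map(lambda n: f"E{n}"),
        )
    )
    def test_idempotent_on_three_digit_codes(self, code):
        assert round_to_three_digit(round_to_three_digit(code)) == round_to_three_digit(code)


class TestFilterNondisease:
    @pytest.mark.parametrize(
        "code,dropped",
        [
            ("650", True),   # pregnancy/childbirth 630–679
            ("630", True),
            ("679", True),
            ("629", False),
            ("680", False),
            ("800", True),   # injury/poisoning 800–999
            ("999", True),
            ("799", False),
            ("V58", True),   # administrative
            ("E880", True),  # external causes
            ("295", False),
            ("038", False),
        ],
    )
    def test_ranges(self, code, dropped):
        kept, report = filter_nondisease([make_record(codes=(code,))])
        assert (len(kept) == 0) == dropped
        assert (sum(report.values()) == 1) == dropped

    def test_idempotent_and_disjoint(self):
        records = [make_record(f"p{i}", codes=(c,))
                   for i, c in enumerate(["650", "V58", "295", "812", "E880", "428"])]
        kept, _ = filter_nondisease(records)
        kept_again, report2 = filter_nondisease(kept)
        assert kept_again == kept
        assert sum(report2.values()) == 0
        assert all(nondisease_category(r.principal_diagnosis) is None for r in kept)


class TestTimelines:
    def test_first_occurrence_collapse(self):
        records = [
            make_record("p", day=0, codes=("295",)),
            make_record("p", day=100, codes=("295",)),
            make_record("p", day=200, codes=("728",)),
        ]
        (tl,) = build_timelines(records)
        assert tl.first_dx_day == {"295": 0, "728": 200}
        assert tl.death_day is None

    def test_death_day_recorded(self):
        records = [make_record("p", day=42, died=True)]
        (tl,) = build_timelines(records)
        assert tl.death_day == 42

    def test_empty_input(self):
        assert build_timelines([]) == []

    def test_records_after_death_dropped(self, caplog):
        records = [
            make_record("p", day=0, codes=("295",), died=True),
            make_record("p", day=50, codes=("728",)),
        ]
        (tl,) = build_timelines(records)
        assert tl.first_dx_day == {"295": 0}
        assert tl.death_day == 0

    def test_code_count_bounded_by_admissions(self):
        records = [make_record("p", day=d, codes=(c,))
                   for d, c in [(0, "295"), (1, "295"), (2, "428")]]
        (tl,) = build_timelines(records)
        assert len(tl.first_dx_day) <= len(records)

    def test_death_day_not_before_diagnoses(self):
        records = [
            make_record("p", day=0, codes=("295",)),
            make_record("p", day=90, codes=("428",), died=True),
        ]
        (tl,) = build_timelines(records)
        assert tl.death_day >= max(tl.first_dx_day.values())


def test_principal_diagnosis():
    assert principal_diagnosis(make_record(codes=("295.3", "728.88"))) == "295.3"
    assert principal_diagnosis(make_record(codes=("038",))) == "038"
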