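"""Readers, field normalization and case deduplication."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitewatch import model
from bitewatch.model import (
    CaseReport,
    FaersFormatError,
    Sex,
    deduplicate_cases,
    normalize_age,
    parse_faers_date,
    read_faers_tables,
)


class TestReaders:
    def test_demo_rows_become_case_reports(self, demo_dir):
        reports = read_faers_tables(demo_dir, "DEMO")
        assert len(reports) == 3
        by_pid = {r.primary_id: r for r in reports}
        assert by_pid["1001"].case_id == "100"
        assert by_pid["1001"].sex is Sex.FEMALE
        assert by_pid["1001"].fda_receipt_date == date(2023, 1, 1)
        assert by_pid["2001"].sex is Sex.UNKNOWN  # UNK code
        assert by_pid["2001"].age_years == 60.0  # 6 decades
        assert by_pid["2001"].country == "Japan"

    def test_trailing_delimiter_ignored(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text(
            "primaryid$caseid$sex\n1$10$F$\n"
        )
        reports = read_faers_tables(tmp_path, "DEMO")
        assert len(reports) == 1 and reports[0].sex is Sex.FEMALE

    def test_missing_required_column_is_format_error(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("primaryid$sex\n1$F\n")
        with pytest.raises(FaersFormatError, match="caseid"):
            read_faers_tables(tmp_path, "DEMO")

    def test_missing_directory_is_input_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_faers_tables(tmp_path / "nope", "DEMO")

    def test_overlong_row_counted_not_fatal(self, tmp_path):
        (tmp_path / "REAC.txt").write_text(
            "primaryid$pt\n1$Tremor\n2$Tremor$extra$junk\n"
        )
        events = read_faers_tables(tmp_path, "REAC")
        assert [e.primary_id for e in events] == ["1"]

    def test_ignored_kinds_accepted(self, demo_dir):
        assert read_faers_tables(demo_dir, "RPSR") == []

    def test_dialect_round_trip(self, demo_dir, tmp_path):
        frame = model.read_table_frame(demo_dir, "DEMO")
        out = tmp_path / "DEMO.txt"
        model.write_table_frame(frame, out)
        again = model.read_table_frame(tmp_path, "DEMO")
        pd.testing.assert_frame_equal(frame, again)


class TestParseDate:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("20230115", date(2023, 1, 15)),
            ("202301", None),  # partial: excluded, not imputed
            ("2023", None),
            ("", None),
            (None, None),
            ("15-JAN-2023", None),
            ("20231301", None),  # impossible month
        ],
    )
    def test_cases(self, raw, expected):
        assert parse_faers_date(raw) == expected


class TestNormalizeAge:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (6, "DEC", 60.0),
            (18, "MON", 1.5),
            (250, "YR", None),  # beyond plausibility bound
            (45, "", 45.0),  # bare value in (0, 120] read as years
            (1500, "", None),
            (-3, "YR", None),
            (36525, "DY", 100.0),
            (52.143, "WK", 1.0),
        ],
    )
    def test_cases(self, value, unit, expected):
        got = normalize_age(value, unit)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


def _report(case_id, version, pid, fda=None):
    return CaseReport(
        primary_id=pid, case_id=case_id, case_version=version, fda_receipt_date=fda
    )


class TestDedup:
    def test_highest_version_kept(self):
        kept = deduplicate_cases([_report("100", 1, "1001"), _report("100", 2, "1002")])
        assert [r.primary_id for r in kept] == ["1002"]

    def test_receipt_date_tiebreak(self):
        kept = deduplicate_cases(
            [
                _report("100", 1, "1001", date(2023, 1, 1)),
                _report("100", 1, "1002", date(2023, 6, 1)),
            ]
        )
        assert kept[0].fda_receipt_date == date(2023, 6, 1)

    def test_primary_id_tiebreak(self):
        kept = deduplicate_cases([_report("100", 1, "9"), _report("100", 1, "10")])
        assert kept[0].primary_id == "10"

    def test_distinct_cases_all_retained(self):
        reports = [_report(str(i), 1, str(1000 + i)) for i in range(5)]
        assert len(deduplicate_cases(reports)) == 5

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),   # case id
                st.integers(0, 4),   # version
                st.integers(0, 99),  # primary id
            ),
            max_size=40,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_idempotent_and_exact(self, triples):
        reports = [_report(str(c), v, str(p)) for c, v, p in triples]
        once = deduplicate_cases(reports)
        assert len(once) == len({r.case_id for r in reports})
        assert sorted(deduplicate_cases(once), key=lambda r: r.case_id) == sorted(
            once, key=lambda r: r.case_id
        )

    def test_frame_dedup_matches_record_dedup(self, demo_dir):
        frame = model.read_table_frame(demo_dir, "DEMO")
        kept_frame = model.dedup_demo_frame(frame)
        kept_records = deduplicate_cases(read_faers_tables(demo_dir, "DEMO"))
        assert set(kept_frame["primaryid"]) == {r.primary_id for r in kept_records}
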