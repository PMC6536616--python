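from datetime import date

import pytest

from bmis_turnover import (
    BmisIOError,
    DumpDialect,
    Phenotype,
    SyntheticConfig,
    filter_window,
    generate_records,
    read_bmis,
    read_cohort,
    write_cohort,
    write_dump,
)
from bmis_turnover.cohort_builder import build_cohort
from bmis_turnover.phenotype import classify_cohort

from conftest import make_record

HEADER = "LAST_NAME|FIRST_NAME|COUNTRY_NAME|RECEIPT_DATE"


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestReadBmis:
    def test_well_formed_file_yields_all_records(self, tmp_path):
        path = write_lines(
            tmp_path / "dump.txt",
            [
                HEADER,
                "SMITH|ANN|USA|2001-01-01",
                "JONES|BOB|CANADA|03/15/2005",
                "LEE|CAT|JAPAN|2015-12-31",
            ],
        )
        records, rejections = read_bmis(path)
        assert rejections == []
        assert [r.last_name for r in records] == ["SMITH", "JONES", "LEE"]
        assert records[1].receipt_date == date(2005, 3, 15)

    def test_bad_date_is_logged_not_dropped_silently(self, tmp_path):
        path = write_lines(
            tmp_path / "dump.txt",
            [
                HEADER,
                "SMITH|ANN|USA|2001-01-01",
                "BAD|ROW|USA|13/45/2001",
                "JONES|BOB|USA|2002-02-02",
            ],
        )
        records, rejections = read_bmis(path)
        assert len(records) == 2
        assert len(rejections) == 1
        assert rejections[0].row_number == 2
        assert "13/45/2001" in rejections[0].reason

    def test_wrong_field_count_rejected(self, tmp_path):
        path = write_lines(
            tmp_path / "dump.txt",
            [HEADER, "SMITH|ANN|USA|2001-01-01", "SHORT|ROW|USA"],
        )
        records, rejections = read_bmis(path)
        assert len(records) == 1 and len(rejections) == 1

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(BmisIOError, match="not found"):
            read_bmis(tmp_path / "absent.txt")

    def test_missing_mapped_columns_fatal_and_named(self, tmp_path):
        path = write_lines(
            tmp_path / "dump.txt", ["LAST_NAME|FIRST_NAME|WHEN", "A|B|2001-01-01"]
        )
        with pytest.raises(BmisIOError) as err:
            read_bmis(path)
        assert "COUNTRY_NAME" in str(err.value) and "RECEIPT_DATE" in str(err.value)

    def test_majority_rejection_means_dialect_mismatch(self, tmp_path):
        path = write_lines(
            tmp_path / "dump.txt",
            [HEADER.replace("|", ","), "A,B,USA,2001-01-01", "C,D,USA,2002-01-01"],
        )
        # comma file read with the default pipe dialect: header check fails first
        with pytest.raises(BmisIOError):
            read_bmis(path)
        bad_dates = [HEADER] + [f"P{i}|Q|USA|not-a-date" for i in range(9)] + [
            "GOOD|ROW|USA|2001-01-01"
        ]
        path2 = write_lines(tmp_path / "dump2.txt", bad_dates)
        with pytest.raises(BmisIOError, match="dialect"):
            read_bmis(path2)

    def test_headerless_dialect_with_index_map(self, tmp_path):
        dialect = DumpDialect(
            delimiter=",",
            has_header=False,
            column_map={
                "last_name": 0,
                "first_name": 1,
                "country_name": 2,
                "receipt_date": 3,
            },
        )
        path = write_lines(
            tmp_path / "dump.txt", ["SMITH,ANN,USA,2001-01-01,extra"]
        )
        records, rejections = read_bmis(path, dialect)
        assert rejections == []
        assert records[0].passthrough == {"COL4": "extra"}

    def test_latin1_fallback(self, tmp_path):
        path = tmp_path / "dump.txt"
        path.write_bytes(
            (HEADER + "\nMU\xdcLLER|J\xd6RG|GERMANY|2001-01-01\n").encode("latin-1")
        )
        records, rejections = read_bmis(path)
        assert records[0].last_name == "MU\xdcLLER"

    def test_synthetic_round_trip_is_field_identical(self, tmp_path):
        records, _ = generate_records(SyntheticConfig(n_investigators=600, seed=7))
        path = tmp_path / "dump.txt"
        write_dump(records, path)
        back, rejections = read_bmis(path)
        assert rejections == []
        assert back == records

    def test_determinism_same_file_same_output(self, tmp_path):
        records, _ = generate_records(SyntheticConfig(n_investigators=100, seed=3))
        path = tmp_path / "dump.txt"
        write_dump(records, path)
        assert read_bmis(path) == read_bmis(path)


class TestFilterWindow:
    def test_year_boundaries_inclusive(self):
        records = [
            make_record(when=date(1998, 12, 31)),
            make_record(when=date(1999, 1, 1)),
            make_record(when=date(2015, 12, 31)),
            make_record(when=date(2016, 1, 1)),
        ]
        kept = filter_window(records, 1999, 2015)
        assert [r.receipt_date.year for r in kept] == [1999, 2015]

    def test_empty_input(self):
        assert filter_window([], 1999, 2015) == []

    def test_inverted_window_fatal(self):
        with pytest.raises(BmisIOError):
            filter_window([], 2015, 1999)

    def test_count_matches_independent_scan(self):
        records, _ = generate_records(
            SyntheticConfig(n_investigators=300, window_start=1995, window_end=2020, seed=5)
        )
        kept = filter_window(records, 1999, 2015)
        expected = sum(1 for r in records if 1999 <= r.receipt_date.year <= 2015)
        assert len(kept) == expected
        # stable order
        assert kept == [r for r in records if 1999 <= r.receipt_date.year <= 2015]


class TestCohortRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        records, _ = generate_records(SyntheticConfig(n_investigators=200, seed=11))
        histories = build_cohort(filter_window(records, 1999, 2015))
        labels, _, _ = classify_cohort(histories)
        path = tmp_path / "cohort.csv"
        write_cohort(histories, labels, path)
        back_h, back_l = read_cohort(path)
        assert back_l == labels
        assert [(h.newid, h.firsub, h.secdiff, h.oad, h.location) for h in back_h] == [
            (h.newid, h.firsub, h.secdiff, h.oad, h.location) for h in histories
        ]

    def test_empty_cohort_writes_header_only(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort([], [], path)
        assert path.read_text().strip() == (
            "newid,last_name,first_name,location,firsub,secdiff,phenotype"
        )
        assert read_cohort(path) == ([], [])

    def test_two_labeled_histories(self, tmp_path, hand_cohort):
        histories = hand_cohort[:2]
        labels = [Phenotype.ONE_AND_DONE, Phenotype.STAYER]
        path = tmp_path / "cohort.csv"
        write_cohort(histories, labels, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3

    def test_malformed_cohort_fatal(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text("not,a,cohort\n1,2,3\n")
        with pytest.raises(BmisIOError):
            read_cohort(path)
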