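"""records_io: CSV dialects, NPI validation, audit-complete reads."""

from __future__ import annotations

import csv

import pytest
from hypothesis import given
from hypothesis import strategies as st

from provlink.directory_update import LinkedProviderRecord
from provlink.errors import ConfigurationError, FormatError
from provlink.matching_engine import MatchType
from provlink.records_io import (
    DIRECTORY_HEADER,
    NPPES_COLUMNS,
    PostalAddress,
    ProviderName,
    TaxonomyCode,
    npi_check_digit,
    read_directory,
    read_licensure_list,
    read_nppes_puf,
    validate_npi,
    write_directory,
    write_licensure_list,
    write_nppes_puf,
)
from provlink.synthetic_data import generate_cohort

from .conftest import make_nppes


# ---------------------------------------------------------------------------
# Independent Luhn oracle (table-driven, distinct from the implementation)
# ---------------------------------------------------------------------------

_DOUBLE = (0, 2, 4, 6, 8, 1, 3, 5, 7, 9)


def luhn_oracle_valid(digits: str) -> bool:
    total = 0
    for pos, ch in enumerate(reversed(digits)):
        d = int(ch)
        total += _DOUBLE[d] if pos % 2 else d
    return total % 10 == 0


class TestValidateNpi:
    def test_too_short(self):
        assert validate_npi("123456789") is False

    def test_non_digits(self):
        assert validate_npi("12345678AB") is False
        assert validate_npi("") is False
        assert validate_npi(None) is False  # type: ignore[arg-type]

    def test_oracle_agreement_on_sampled_prefix(self):
        # brute-force the check digit with the independent oracle
        prefix = "123456789"
        valid = [d for d in "0123456789" if luhn_oracle_valid("80840" + prefix + d)]
        assert valid == ["3"]  # frozen from the oracle
        assert validate_npi(prefix + "3") is True
        assert validate_npi(prefix + "4") is False

    @given(st.integers(min_value=0, max_value=999_999_999))
    def test_exactly_one_check_digit_per_prefix(self, base):
        prefix = f"{base:09d}"
        accepted = [d for d in "0123456789" if validate_npi(prefix + d)]
        oracle = [d for d in "0123456789" if luhn_oracle_valid("80840" + prefix + d)]
        assert len(accepted) == 1
        assert accepted == oracle

    @given(st.integers(min_value=0, max_value=999_999_999))
    def test_check_digit_helper_round_trips(self, base):
        prefix = f"{base:09d}"
        digit = npi_check_digit(prefix)
        assert validate_npi(prefix + str(digit))
        assert not validate_npi(prefix + str((digit + 1) % 10))


# ---------------------------------------------------------------------------
# Licensure reader
# ---------------------------------------------------------------------------

def _write_licensure_csv(path, rows, header=None):
    header = header or [
        "license_number", "first_name", "middle_name", "last_name",
        "suffix", "street", "city", "state", "zip",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _row(license_number, first="Helen", last="Black"):
    return [license_number, first, "", last, "", "1705 Park Ave", "Hartford", "CT", "06101"]


class TestReadLicensure:
    def test_three_distinct_rows(self, tmp_path):
        p = tmp_path / "lic.csv"
        _write_licensure_csv(p, [_row("1"), _row("2"), _row("3")])
        res = read_licensure_list(p, "dentist", 2017)
        assert len(res.records) == 3
        assert res.records[0].provider_type == "dentist"
        assert res.records[0].year == 2017

    def test_duplicate_license_collapsed_and_logged(self, tmp_path):
        p = tmp_path / "lic.csv"
        _write_licensure_csv(p, [_row("005577", first="Helen"), _row("005577", first="Ellen")])
        res = read_licensure_list(p, "dentist", 2017)
        assert len(res.records) == 1
        assert res.records[0].name.first == "Helen"  # first occurrence wins
        assert res.duplicate_licenses == ["005577"]

    def test_empty_last_name_dropped_and_counted(self, tmp_path):
        p = tmp_path / "lic.csv"
        _write_licensure_csv(p, [_row("1"), _row("2", last="")])
        res = read_licensure_list(p, "dentist", 2017)
        assert len(res.records) == 1
        assert res.dropped_empty_last == 1

    def test_row_count_conservation(self, tmp_path):
        p = tmp_path / "lic.csv"
        _write_licensure_csv(p, [_row("1"), _row("1"), _row("2", last=""), _row("3")])
        res = read_licensure_list(p, "dentist", 2017)
        assert res.n_rows == len(res.records) + res.n_dropped

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_licensure_list(tmp_path / "nope.csv", "dentist", 2017)

    def test_unknown_provider_type(self, tmp_path):
        p = tmp_path / "lic.csv"
        _write_licensure_csv(p, [_row("1")])
        with pytest.raises(ConfigurationError, match="physician"):
            read_licensure_list(p, "physician", 2017)

    def test_malformed_header_names_missing_column(self, tmp_path):
        p = tmp_path / "lic.csv"
        _write_licensure_csv(
            p, [["1", "Helen"]], header=["license_number", "first_name"]
        )
        with pytest.raises(FormatError, match="last_name"):
            read_licensure_list(p, "dentist", 2017)

    def test_custom_column_map(self, tmp_path):
        p = tmp_path / "lic.csv"
        with open(p, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["LIC NO", "FIRST", "LAST", "ADDR", "TOWN"])
            writer.writerow(["9", "Helen", "Black", "37 Collins Road", "Avon"])
        res = read_licensure_list(
            p, "dentist", 2017,
            column_map={
                "license_number": "LIC NO", "first_name": "FIRST",
                "last_name": "LAST", "street": "ADDR", "city": "TOWN",
            },
        )
        assert res.records[0].name.last == "Black"
        assert res.records[0].address.street == "37 Collins Road"

    def test_cnm_style_fixture_of_231_records(self, tmp_path):
        cohort = generate_cohort(231, provider_type="certified_nurse_midwife",
                                 seed=231, out_dir=tmp_path)
        res = read_licensure_list(cohort.paths["licensure"], "certified_nurse_midwife", 2017)
        assert len(res.records) == 231

    def test_round_trip(self, tmp_path):
        cohort = generate_cohort(20, seed=5)
        p = tmp_path / "lic.csv"
        write_licensure_list(cohort.licensure, p)
        res = read_licensure_list(p, "certified_nurse_midwife", 2017)
        assert res.records == cohort.licensure


# ---------------------------------------------------------------------------
# NPPES reader
# ---------------------------------------------------------------------------

class TestReadNppes:
    def test_round_trip_with_both_taxonomies(self, tmp_path):
        rec = make_nppes(tax1="367A00000X", tax2="176B00000X")
        p = tmp_path / "nppes.csv"
        write_nppes_puf([rec], p)
        res = read_nppes_puf(p, 2017)
        assert res.records == [rec]
        assert res.records[0].taxonomy_secondary == TaxonomyCode("176B00000X")

    def test_invalid_check_digit_quarantined(self, tmp_path):
        flipped = "1234567894"  # valid NPI with last digit +1: fails the oracle
        assert not luhn_oracle_valid("80840" + flipped)
        p = tmp_path / "nppes.csv"
        write_nppes_puf([make_nppes(npi="1234567893")], p)
        lines = p.read_text().splitlines()
        bad_line = lines[1].replace("1234567893", flipped).replace("Helen", "Eve")
        p.write_text("\n".join([lines[0], lines[1], bad_line]) + "\n")
        res = read_nppes_puf(p, 2017)
        assert len(res.records) == 1
        assert len(res.quarantined) == 1
        assert res.quarantined[0][1] == "invalid_npi"
        assert res.n_rows == len(res.records) + res.n_quarantined

    def test_duplicate_npi_quarantined(self, tmp_path):
        p = tmp_path / "nppes.csv"
        write_nppes_puf([make_nppes(), make_nppes(first="Ellen")], p)
        res = read_nppes_puf(p, 2017)
        assert len(res.records) == 1
        assert res.quarantined[0][1] == "duplicate_npi"

    def test_empty_gender_becomes_unknown(self, tmp_path):
        p = tmp_path / "nppes.csv"
        write_nppes_puf([make_nppes(gender="unknown")], p)
        res = read_nppes_puf(p, 2017)
        assert res.records[0].gender == "unknown"

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "nppes.csv"
        p.write_text("NPI,Provider First Name\n1234567893,Helen\n")
        with pytest.raises(FormatError, match="Last Name"):
            read_nppes_puf(p, 2017)

    def test_other_identifiers_round_trip(self, tmp_path):
        rec = make_nppes()
        rec = type(rec)(**{**rec.__dict__, "other_identifiers": (("CT", "001122"),)})
        p = tmp_path / "nppes.csv"
        write_nppes_puf([rec], p)
        res = read_nppes_puf(p, 2017)
        assert res.records[0].other_identifiers == (("CT", "001122"),)


# ---------------------------------------------------------------------------
# Directory writer
# ---------------------------------------------------------------------------

def _linked(license_number="001122", npi="1234567893", score=20):
    return LinkedProviderRecord(
        legal_name=ProviderName(first="Helen", last="Black"),
        npi=npi,
        gender="F",
        phone="8605550100",
        taxonomy=TaxonomyCode("367A00000X"),
        practice_address=PostalAddress(street="1705 Park Ave", city="Hartford",
                                       state="CT", zip="06101"),
        mailing_address=PostalAddress(street="1705 Park Ave", city="Hartford",
                                      state="CT", zip="06101"),
        other_identifiers=(),
        license_number=license_number,
        match_type=MatchType.FL_CS,
        total_score=score,
    )


class TestWriteDirectory:
    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "dir.csv"
        assert write_directory([], p) == 0
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == list(DIRECTORY_HEADER)

    def test_five_records_returns_five(self, tmp_path):
        recs = [_linked(license_number=str(i), npi=_npi(i)) for i in range(5)]
        assert write_directory(recs, tmp_path / "dir.csv") == 5

    def test_round_trip_identity(self, tmp_path):
        recs = [_linked(license_number=str(i), npi=_npi(i)) for i in range(4)]
        p = tmp_path / "dir.csv"
        write_directory(recs, p)
        assert read_directory(p) == recs


def _npi(i: int) -> str:
    base = f"1{i:08d}"
    return base + str(npi_check_digit(base))
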