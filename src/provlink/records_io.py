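"""Readers/writers for the three CSV dialects used by the pipeline.

Three files flow through the system:

* a state licensure roster (one file per provider type per snapshot year,
  configurable column names),
* a national provider snapshot using the NPPES public-use-file column
  naming convention (subset of columns only),
* the merged output directory (fixed header).

All files are comma-separated, RFC-4180 quoted, UTF-8, with a mandatory
header row.  Readers never silently drop rows: rows removed by the
duplicate-license rule or by NPI validation are counted (and, for NPPES,
retained on a quarantine list) so that ``rows_in == records_out + dropped``
always holds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, FormatError

PROVIDER_TYPES: tuple[str, ...] = (
    "certified_nurse_midwife",
    "nurse_practitioner",
    "dentist",
)

GENDERS = ("M", "F", "unknown")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProviderName:
    """A person name split into components; ``raw`` preserves the input."""

    first: str
    middle: str = ""
    last: str = ""
    suffix: str = ""
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.raw:
            parts = [self.first, self.middle, self.last, self.suffix]
            object.__setattr__(self, "raw", " ".join(p for p in parts if p))


@dataclass(frozen=True)
class PostalAddress:
    """A postal address; ``state`` is a two-letter code or empty."""

    street: str = ""
    city: str = ""
    state: str = ""
    zip: str = ""
    raw: str = ""

    def __post_init__(self) -> None:
        st = self.state.strip().upper()
        if st and not (len(st) == 2 and st.isalpha()):
            raise FormatError(f"state must be a two-letter code or empty: {self.state!r}")
        object.__setattr__(self, "state", st)
        if not self.raw:
            parts = [self.street, self.city, self.state, self.zip]
            object.__setattr__(self, "raw", ", ".join(p for p in parts if p))


@dataclass(frozen=True)
class TaxonomyCode:
    """A 10-character NUCC taxonomy code (terminal 'X') with optional label."""

    code: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", self.code.strip().upper())

    @property
    def valid(self) -> bool:
        return is_valid_taxonomy(self.code)


def is_valid_taxonomy(code: str) -> bool:
    """True iff *code* has the general NUCC shape: 10 alphanumerics ending in X."""
    code = code.strip().upper()
    return len(code) == 10 and code.endswith("X") and code.isalnum()


@dataclass(frozen=True)
class LicensureRecord:
    license_number: str
    provider_type: str
    name: ProviderName
    address: PostalAddress
    year: int


@dataclass(frozen=True)
class NPPESRecord:
    npi: str
    name: ProviderName
    gender: str
    phone: str
    taxonomy_primary: TaxonomyCode
    taxonomy_secondary: TaxonomyCode | None
    mailing_address: PostalAddress
    practice_address: PostalAddress
    other_identifiers: tuple[tuple[str, str], ...]
    year: int


# ---------------------------------------------------------------------------
# NPI validation
# ---------------------------------------------------------------------------

_NPI_PREFIX = "80840"  # ISO 7812 health-industry issuer prefix


def _luhn_checksum(digits: str) -> int:
    total = 0
    for i, ch in enumerate(reversed(digits)):
        d = int(ch)
        if i % 2 == 1:
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return total % 10


def validate_npi(s: str) -> bool:
    """Check that *s* is a 10-digit NPI with a correct Luhn check digit.

    The check digit is computed over the 9-digit base prefixed with 80840.
    Returns ``False`` for any malformed input; never raises.
    """
    if not isinstance(s, str):
        return False
    s = s.strip()
    if len(s) != 10 or not s.isdigit():
        return False
    return _luhn_checksum(_NPI_PREFIX + s) == 0


def npi_check_digit(base9: str) -> int:
    """Return the check digit completing a 9-digit NPI base."""
    if len(base9) != 9 or not base9.isdigit():
        raise ValueError(f"need a 9-digit base, got {base9!r}")
    partial = _luhn_checksum(_NPI_PREFIX + base9 + "0")
    return (10 - partial) % 10


# ---------------------------------------------------------------------------
# Licensure roster reader
# ---------------------------------------------------------------------------

#: logical field -> default column header for licensure rosters
DEFAULT_LICENSURE_COLUMNS: Mapping[str, str] = {
    "license_number": "license_number",
    "first_name": "first_name",
    "middle_name": "middle_name",
    "last_name": "last_name",
    "suffix": "suffix",
    "street": "street",
    "city": "city",
    "state": "state",
    "zip": "zip",
}

_LICENSURE_REQUIRED = ("license_number", "first_name", "last_name", "street", "city")


@dataclass
class LicensureReadResult:
    """Records plus the per-row audit trail of the read."""

    records: list[LicensureRecord]
    n_rows: int
    dropped_empty_last: int = 0
    duplicate_licenses: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.dropped_empty_last + len(self.duplicate_licenses)


def read_licensure_list(
    path: str | Path,
    provider_type: str,
    year: int,
    column_map: Mapping[str, str] | None = None,
) -> LicensureReadResult:
    """Read one licensure roster file.

    Rows with an empty last name are dropped (counted); duplicate license
    numbers collapse to the first occurrence (counted) — licensure rosters
    are known to carry duplicate rows.
    """
    if provider_type not in PROVIDER_TYPES:
        raise ConfigurationError(
            f"unknown provider_type {provider_type!r}; supported: {', '.join(PROVIDER_TYPES)}"
        )
    cols = dict(DEFAULT_LICENSURE_COLUMNS)
    if column_map:
        cols.update(column_map)

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in _LICENSURE_REQUIRED:
            if cols[logical] not in header:
                raise FormatError(
                    f"licensure file {path} is missing column {cols[logical]!r}"
                )
        result = LicensureReadResult(records=[], n_rows=0)
        seen: set[str] = set()
        for row in reader:
            result.n_rows += 1
            get = lambda logical: (row.get(cols[logical]) or "").strip()  # noqa: E731
            last = get("last_name")
            if not last:
                result.dropped_empty_last += 1
                continue
            lic = get("license_number")
            if lic in seen:
                result.duplicate_licenses.append(lic)
                continue
            seen.add(lic)
            name = ProviderName(
                first=get("first_name"),
                middle=get("middle_name"),
                last=last,
                suffix=get("suffix"),
            )
            addr = PostalAddress(
                street=get("street"), city=get("city"),
                state=get("state"), zip=get("zip"),
            )
            result.records.append(
                LicensureRecord(
                    license_number=lic, provider_type=provider_type,
                    name=name, address=addr, year=year,
                )
            )
    return result


def write_licensure_list(
    records: Iterable[LicensureRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> int:
    cols = dict(DEFAULT_LICENSURE_COLUMNS)
    if column_map:
        cols.update(column_map)
    order = list(DEFAULT_LICENSURE_COLUMNS)
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([cols[c] for c in order])
        for rec in records:
            writer.writerow([
                rec.license_number,
                rec.name.first, rec.name.middle, rec.name.last, rec.name.suffix,
                rec.address.street, rec.address.city, rec.address.state, rec.address.zip,
            ])
            n += 1
    return n


# ---------------------------------------------------------------------------
# NPPES public-use-file subset reader
# ---------------------------------------------------------------------------

NPPES_COLUMNS: Mapping[str, str] = {
    "npi": "NPI",
    "last_name": "Provider Last Name (Legal Name)",
    "first_name": "Provider First Name",
    "middle_name": "Provider Middle Name",
    "suffix": "Provider Name Suffix Text",
    "gender": "Provider Gender Code",
    "phone": "Provider Business Practice Location Address Telephone Number",
    "tax1": "Healthcare Provider Taxonomy Code_1",
    "tax2": "Healthcare Provider Taxonomy Code_2",
    "mail_street": "Provider First Line Business Mailing Address",
    "mail_city": "Provider Business Mailing Address City Name",
    "mail_state": "Provider Business Mailing Address State Name",
    "mail_zip": "Provider Business Mailing Address Postal Code",
    "prac_street": "Provider First Line Business Practice Location Address",
    "prac_city": "Provider Business Practice Location Address City Name",
    "prac_state": "Provider Business Practice Location Address State Name",
    "prac_zip": "Provider Business Practice Location Address Postal Code",
    "other_id_1": "Other Provider Identifier_1",
    "other_issuer_1": "Other Provider Identifier Issuer_1",
    "other_id_2": "Other Provider Identifier_2",
    "other_issuer_2": "Other Provider Identifier Issuer_2",
}

_NPPES_REQUIRED = ("npi", "last_name", "first_name", "tax1",
                   "prac_street", "prac_city", "prac_state")


@dataclass
class NppesReadResult:
    records: list[NPPESRecord]
    n_rows: int
    quarantined: list[tuple[dict, str]] = field(default_factory=list)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)


def read_nppes_puf(path: str | Path, year: int) -> NppesReadResult:
    """Read an NPPES-PUF-style snapshot (subset of official columns).

    Rows whose NPI fails check-digit validation, and rows repeating an NPI
    already seen in the snapshot, are quarantined — kept on a reject list
    with a reason, never silently dropped.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in _NPPES_REQUIRED:
            if NPPES_COLUMNS[logical] not in header:
                raise FormatError(f"NPPES file {path} is missing column {NPPES_COLUMNS[logical]!r}")
        result = NppesReadResult(records=[], n_rows=0)
        seen: set[str] = set()
        for row in reader:
            result.n_rows += 1
            get = lambda logical: (row.get(NPPES_COLUMNS[logical]) or "").strip()  # noqa: E731
            npi = get("npi")
            if not validate_npi(npi):
                result.quarantined.append((dict(row), "invalid_npi"))
                continue
            if npi in seen:
                result.quarantined.append((dict(row), "duplicate_npi"))
                continue
            seen.add(npi)
            gender = get("gender").upper()
            if gender not in ("M", "F"):
                gender = "unknown"
            tax2_code = get("tax2")
            others = []
            for slot in ("1", "2"):
                value = get(f"other_id_{slot}")
                if value:
                    others.append((get(f"other_issuer_{slot}"), value))
            result.records.append(
                NPPESRecord(
                    npi=npi,
                    name=ProviderName(
                        first=get("first_name"), middle=get("middle_name"),
                        last=get("last_name"), suffix=get("suffix"),
                    ),
                    gender=gender,
                    phone=get("phone"),
                    taxonomy_primary=TaxonomyCode(get("tax1")),
                    taxonomy_secondary=TaxonomyCode(tax2_code) if tax2_code else None,
                    mailing_address=PostalAddress(
                        street=get("mail_street"), city=get("mail_city"),
                        state=get("mail_state"), zip=get("mail_zip"),
                    ),
                    practice_address=PostalAddress(
                        street=get("prac_street"), city=get("prac_city"),
                        state=get("prac_state"), zip=get("prac_zip"),
                    ),
                    other_identifiers=tuple(others),
                    year=year,
                )
            )
    return result


def write_nppes_puf(records: Iterable[NPPESRecord], path: str | Path) -> int:
    order = list(NPPES_COLUMNS)
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([NPPES_COLUMNS[c] for c in order])
        for rec in records:
            others = list(rec.other_identifiers) + [("", ""), ("", "")]
            writer.writerow([
                rec.npi,
                rec.name.last, rec.name.first, rec.name.middle, rec.name.suffix,
                "" if rec.gender == "unknown" else rec.gender,
                rec.phone,
                rec.taxonomy_primary.code,
                rec.taxonomy_secondary.code if rec.taxonomy_secondary else "",
                rec.mailing_address.street, rec.mailing_address.city,
                rec.mailing_address.state, rec.mailing_address.zip,
                rec.practice_address.street, rec.practice_address.city,
                rec.practice_address.state, rec.practice_address.zip,
                others[0][1], others[0][0],
                others[1][1], others[1][0],
            ])
            n += 1
    return n


def write_quarantine(quarantined: Sequence[tuple[dict, str]], path: str | Path) -> int:
    """Write quarantined NPPES rows with their rejection reason."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        if not quarantined:
            fh.write("reason\n")
            return 0
        fieldnames = list(quarantined[0][0]) + ["reason"]
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row, reason in quarantined:
            writer.writerow({**row, "reason": reason})
    return len(quarantined)


# ---------------------------------------------------------------------------
# Output directory file
# ---------------------------------------------------------------------------

DIRECTORY_HEADER: tuple[str, ...] = (
    "last_name", "first_name", "npi", "gender", "phone", "taxonomy_code",
    "practice_street", "practice_city", "practice_state", "practice_zip",
    "mailing_street", "mailing_city", "mailing_state", "mailing_zip",
    "license_number", "match_type", "total_score",
)


def write_directory(records: Sequence, path: str | Path) -> int:
    """Write merged directory records (fixed header); returns the row count.

    ``records`` are :class:`~provlink.directory_update.LinkedProviderRecord`
    instances (imported lazily to keep module layering acyclic).
    """
    n = 0
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DIRECTORY_HEADER)
        for rec in records:
            writer.writerow([
                rec.legal_name.last, rec.legal_name.first,
                rec.npi, rec.gender, rec.phone, rec.taxonomy.code,
                rec.practice_address.street, rec.practice_address.city,
                rec.practice_address.state, rec.practice_address.zip,
                rec.mailing_address.street, rec.mailing_address.city,
                rec.mailing_address.state, rec.mailing_address.zip,
                rec.license_number, rec.match_type.name, rec.total_score,
            ])
            n += 1
    return n


def read_directory(path: str | Path) -> list:
    """Read back an output directory file (round-trip inverse of write)."""
    from .directory_update import LinkedProviderRecord
    from .matching_engine import MatchType

    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != DIRECTORY_HEADER:
            raise FormatError(f"unexpected directory header in {path}")
        for row in reader:
            out.append(
                LinkedProviderRecord(
                    legal_name=ProviderName(first=row["first_name"], last=row["last_name"]),
                    npi=row["npi"],
                    gender=row["gender"],
                    phone=row["phone"],
                    taxonomy=TaxonomyCode(row["taxonomy_code"]),
                    practice_address=PostalAddress(
                        street=row["practice_street"], city=row["practice_city"],
                        state=row["practice_state"], zip=row["practice_zip"],
                    ),
                    mailing_address=PostalAddress(
                        street=row["mailing_street"], city=row["mailing_city"],
                        state=row["mailing_state"], zip=row["mailing_zip"],
                    ),
                    other_identifiers=(),
                    license_number=row["license_number"],
                    match_type=MatchType[row["match_type"]],
                    total_score=int(row["total_score"]),
                )
            )
    return out


__all__ = [
    "PROVIDER_TYPES", "GENDERS",
    "ProviderName", "PostalAddress", "TaxonomyCode", "LicensureRecord", "NPPESRecord",
    "is_valid_taxonomy", "validate_npi", "npi_check_digit",
    "DEFAULT_LICENSURE_COLUMNS", "NPPES_COLUMNS", "DIRECTORY_HEADER",
    "LicensureReadResult", "NppesReadResult",
    "read_licensure_list", "write_licensure_list",
    "read_nppes_puf", "write_nppes_puf", "write_quarantine",
    "write_directory", "read_directory",
]
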