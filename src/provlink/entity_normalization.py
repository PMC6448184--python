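"""Canonical keys for names and addresses, plus the string-distance primitive.

Everything the matcher compares goes through this module first: names and
addresses are uppercased, stripped of punctuation, and reduced to stable
keys; street suffixes are canonicalized to their USPS abbreviations so that
"1705 Park Avenue" and "1705 Park Ave" compare equal.  The Levenshtein
primitive and the tiered fuzzy-equality rule used for misspelling tolerance
live here too.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .records_io import LicensureRecord, NPPESRecord, PostalAddress, ProviderName

#: default location filter: the study state, its neighbours, and Florida
DEFAULT_STATES: frozenset[str] = frozenset({"CT", "MA", "NY", "RI", "FL"})

_GENERATIONAL_SUFFIXES = {"JR", "SR", "II", "III", "IV"}

_UNIT_DESIGNATORS = {
    "APT", "APARTMENT", "STE", "SUITE", "UNIT", "FL", "FLOOR",
    "RM", "ROOM", "BLDG", "BUILDING", "DEPT", "#",
}

_PUNCT_RE = re.compile(r"[^A-Z0-9# ]+")
# apostrophes and periods join fragments (O'NEIL -> ONEIL, ST. -> ST);
# other punctuation separates them (BROWN-SMITH -> BROWN SMITH)
_JOINING_PUNCT_RE = re.compile(r"['.’]")


def _load_suffix_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("provlink").joinpath("resources/street_suffixes.txt").read_text("utf-8")
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        variant, canonical = line.split("\t")
        table[variant] = canonical
    return table


_SUFFIX_TABLE = _load_suffix_table()


def normalize_token(s: str) -> str:
    """Uppercase, drop punctuation, collapse whitespace."""
    s = _JOINING_PUNCT_RE.sub("", s.upper())
    s = _PUNCT_RE.sub(" ", s)
    return " ".join(s.split())


# ---------------------------------------------------------------------------
# Names
# ---------------------------------------------------------------------------

def normalize_person_name(name: ProviderName) -> tuple[str, str, tuple[str, ...]]:
    """Return ``(first_key, last_key, last_tokens)``.

    Generational suffixes (JR, SR, II, III, IV) are removed whether they
    arrived in the suffix field or trailing the last name; hyphenated and
    compound surnames are tokenized ("BROWN-SMITH" -> ("BROWN", "SMITH")).
    """
    first_key = normalize_token(name.first).replace("#", "").strip()
    first_key = first_key.split()[0] if first_key else ""
    last = normalize_token(name.last).replace("#", "").strip()
    tokens = tuple(t for t in last.split() if t not in _GENERATIONAL_SUFFIXES)
    return first_key, " ".join(tokens), tokens


# ---------------------------------------------------------------------------
# Addresses
# ---------------------------------------------------------------------------

def normalize_address(addr: PostalAddress) -> tuple[str, str]:
    """Return ``(city_key, street_key)``.

    The street key has USPS-canonical suffixes and no unit/suite tail; an
    empty street yields an empty key (the record stays matchable on
    name + city).
    """
    city_key = normalize_token(addr.city).replace("#", "").strip()
    tokens = normalize_token(addr.street).split()
    kept: list[str] = []
    for tok in tokens:
        if tok in _UNIT_DESIGNATORS or tok.startswith("#"):
            break  # unit designator starts the droppable tail
        kept.append(_SUFFIX_TABLE.get(tok, tok))
    return city_key, " ".join(kept)


def split_street_number(street_key: str) -> tuple[str, str]:
    """Split a normalized street key into (house number, rest)."""
    parts = street_key.split(None, 1)
    if parts and parts[0].isdigit():
        return parts[0], parts[1] if len(parts) > 1 else ""
    return "", street_key


# ---------------------------------------------------------------------------
# Normalized key bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedEntityKey:
    """The comparison keys for one record.

    For national records, which carry both a practice and a mailing
    address, ``city_key``/``street_key`` come from the practice address and
    ``alt_city_key``/``alt_street_key`` from the mailing address; for
    licensure records the alt keys are empty.
    """

    first_key: str
    last_key: str
    last_tokens: tuple[str, ...]
    city_key: str
    street_key: str
    alt_city_key: str = ""
    alt_street_key: str = ""


def normalized_key(record: LicensureRecord | NPPESRecord) -> NormalizedEntityKey:
    first_key, last_key, last_tokens = normalize_person_name(record.name)
    if isinstance(record, NPPESRecord):
        p_city, p_street = normalize_address(record.practice_address)
        m_city, m_street = normalize_address(record.mailing_address)
        return NormalizedEntityKey(
            first_key=first_key, last_key=last_key, last_tokens=last_tokens,
            city_key=p_city, street_key=p_street,
            alt_city_key=m_city, alt_street_key=m_street,
        )
    city, street = normalize_address(record.address)
    return NormalizedEntityKey(
        first_key=first_key, last_key=last_key, last_tokens=last_tokens,
        city_key=city, street_key=street,
    )


# ---------------------------------------------------------------------------
# Location filter
# ---------------------------------------------------------------------------

def filter_by_location(
    records: Sequence[NPPESRecord],
    states: Iterable[str] = DEFAULT_STATES,
) -> list[NPPESRecord]:
    """Keep records whose practice OR mailing address is in *states*."""
    state_set = {s.strip().upper() for s in states}
    if not state_set:
        raise ConfigurationError("location filter requires a non-empty state set")
    return [
        rec for rec in records
        if rec.practice_address.state in state_set or rec.mailing_address.state in state_set
    ]


# ---------------------------------------------------------------------------
# String distance
# ---------------------------------------------------------------------------

def name_edit_distance(a: str, b: str) -> int:
    """Levenshtein distance with unit insert/delete/substitute costs."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def within_distance(a: str, b: str, k: int) -> bool:
    """True iff Levenshtein(a, b) <= k; banded DP with early abandon."""
    if a == b:
        return True
    if k <= 0:
        return False
    la, lb = len(a), len(b)
    if abs(la - lb) > k:
        return False
    if la < lb:
        a, b, la, lb = b, a, lb, la
    if lb == 0:
        return la <= k
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        lo = max(1, i - k)
        hi = min(lb, i + k)
        cur = [i] + [k + 1] * lb
        ca = a[i - 1]
        for j in range(lo, hi + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != b[j - 1]))
        if min(cur[lo:hi + 1]) > k:
            return False
        prev = cur
    return prev[lb] <= k


def fuzzy_tolerance(a: str, b: str) -> int:
    """Edit tolerance tier: <=2 when the longer key has >= 5 chars, else <=1."""
    return 2 if max(len(a), len(b)) >= 5 else 1


def keys_equal(a: str, b: str, fuzzy: bool) -> bool:
    """Entity-key equality under the configured mode.

    Empty keys never match anything (absence of evidence is not agreement).
    """
    if not a or not b:
        return False
    if a == b:
        return True
    if not fuzzy:
        return False
    return within_distance(a, b, fuzzy_tolerance(a, b))


__all__ = [
    "DEFAULT_STATES", "NormalizedEntityKey",
    "normalize_token", "normalize_person_name", "normalize_address",
    "split_street_number", "normalized_key", "filter_by_location",
    "name_edit_distance", "within_distance", "fuzzy_tolerance", "keys_equal",
]
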