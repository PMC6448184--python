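"""Candidate-pair classification into the seven name/address match types.

A candidate (licensure, national) pair is classified by which entities
agree under the configured equality rule: the full-name family
{first+last} × {city+street, city, street, neither} and the surname family
{last only} × {city+street, city, street}.  A bare surname match with no
corroborating address is not a match type — last-name agreement is a hard
requirement for every type, and a pair whose surnames disagree is NONE.

Blocking restricts pair generation to records sharing a surname-token
signature.  In fuzzy mode the signature is the depth-2 deletion
neighbourhood of each surname token, which is complete for the configured
edit tolerance: if two tokens are within Levenshtein distance 2, deleting
the edited positions from each side leaves a common variant, so the pair
is guaranteed to share a block key.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_RANK_ORDER, MatchingConfig, RunConfig
from .entity_normalization import (
    NormalizedEntityKey,
    keys_equal,
    normalized_key,
    split_street_number,
)
from .errors import ConfigurationError
from .records_io import LicensureRecord, NPPESRecord
from .temporal_scoring import EntityScoreVector


class MatchType(enum.Enum):
    """The seven match types plus NONE; default rank is the enum value."""

    FL_CS = 1
    FL_C = 2
    FL_S = 3
    FL = 4
    L_CS = 5
    L_C = 6
    L_S = 7
    NONE = 8

    @property
    def rank(self) -> int | None:
        return None if self is MatchType.NONE else self.value


#: entities (beyond last name) each type requires to agree
_REQUIREMENTS: Mapping[str, frozenset[str]] = {
    "FL_CS": frozenset({"first", "city", "street"}),
    "FL_C": frozenset({"first", "city"}),
    "FL_S": frozenset({"first", "street"}),
    "FL": frozenset({"first"}),
    "L_CS": frozenset({"city", "street"}),
    "L_C": frozenset({"city"}),
    "L_S": frozenset({"street"}),
}


def enumerate_match_types(config: MatchingConfig | None = None) -> list[MatchType]:
    """The seven non-NONE match types, strongest first."""
    order = (config.rank_order if config is not None else DEFAULT_RANK_ORDER)
    return [MatchType[code] for code in order]


def rank_of(match_type: MatchType, config: MatchingConfig | None = None) -> int:
    order = (config.rank_order if config is not None else DEFAULT_RANK_ORDER)
    return order.index(match_type.name) + 1


@dataclass
class MatchCandidate:
    """One putative identity: a (licensure record, NPI) pair over the window."""

    licensure: LicensureRecord
    nppes: NPPESRecord
    match_type: MatchType
    entity_years: dict[str, set[int]] = field(default_factory=dict)
    matched_years: set[int] = field(default_factory=set)
    scores: EntityScoreVector | None = None
    total: int = 0

    @property
    def recent_year(self) -> int:
        return max(self.matched_years)


# ---------------------------------------------------------------------------
# Entity agreement
# ---------------------------------------------------------------------------

def _first_names_agree(a: str, b: str, fuzzy: bool) -> bool:
    if not a or not b:
        return False
    # a bare initial agrees with a full name starting with it
    if len(a) == 1 or len(b) == 1:
        return a[0] == b[0]
    return keys_equal(a, b, fuzzy)


def _last_names_agree(a_tokens: tuple[str, ...], b_tokens: tuple[str, ...], fuzzy: bool) -> bool:
    """Token-subset rule: compound surnames agree when one token set is a
    subset of the other under the per-token equality rule."""
    if not a_tokens or not b_tokens:
        return False
    small, large = (a_tokens, b_tokens) if len(a_tokens) <= len(b_tokens) else (b_tokens, a_tokens)
    return all(any(keys_equal(t, u, fuzzy) for u in large) for t in small)


def _streets_agree(a: str, b: str, fuzzy: bool) -> bool:
    if not a or not b:
        return False
    if a == b:
        return True
    # house numbers must agree exactly; only the street name is fuzzy-tolerant
    na, ra = split_street_number(a)
    nb, rb = split_street_number(b)
    return na == nb and keys_equal(ra, rb, fuzzy)


_NO_MATCH = {"last": False, "first": False, "city": False, "street": False}


def _agreements(lic: NormalizedEntityKey, rec: NormalizedEntityKey, fuzzy: bool) -> dict[str, bool]:
    # surname agreement is required by every match type; skip the rest early
    if not _last_names_agree(lic.last_tokens, rec.last_tokens, fuzzy):
        return _NO_MATCH
    return {
        "last": True,
        "first": _first_names_agree(lic.first_key, rec.first_key, fuzzy),
        "city": (
            keys_equal(lic.city_key, rec.city_key, fuzzy)
            or keys_equal(lic.city_key, rec.alt_city_key, fuzzy)
        ),
        "street": (
            _streets_agree(lic.street_key, rec.street_key, fuzzy)
            or _streets_agree(lic.street_key, rec.alt_street_key, fuzzy)
        ),
    }


def _type_from_agreements(agree: Mapping[str, bool], order: Sequence[str]) -> MatchType:
    if not agree["last"]:
        return MatchType.NONE
    have = {e for e in ("first", "city", "street") if agree[e]}
    for code in order:
        if _REQUIREMENTS[code] <= have:
            return MatchType[code]
    return MatchType.NONE


def classify_match(
    lic: LicensureRecord,
    rec: NPPESRecord,
    config: RunConfig | MatchingConfig | None = None,
) -> MatchType:
    """Classify one pair into the strongest match type its agreements allow."""
    matching = _matching_config(config)
    agree = _agreements(normalized_key(lic), normalized_key(rec), matching.fuzzy)
    return _type_from_agreements(agree, matching.rank_order)


def _matching_config(config: RunConfig | MatchingConfig | None) -> MatchingConfig:
    if config is None:
        return MatchingConfig()
    if isinstance(config, RunConfig):
        return config.matching
    return config


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------

def _deletion_variants(s: str, depth: int) -> set[str]:
    out = {s}
    frontier = {s}
    for _ in range(depth):
        nxt = set()
        for t in frontier:
            for i in range(len(t)):
                nxt.add(t[:i] + t[i + 1:])
        nxt -= out
        out |= nxt
        frontier = nxt
    return out


def _block_keys(key: NormalizedEntityKey, depth: int) -> set[str]:
    keys: set[str] = set()
    for token in key.last_tokens:
        keys |= _deletion_variants(token, depth)
    return keys


def block_candidates(
    lic_list: Sequence[LicensureRecord],
    nppes_list: Sequence[NPPESRecord],
    config: RunConfig | MatchingConfig | None = None,
) -> list[tuple[LicensureRecord, NPPESRecord]]:
    """Emit candidate pairs sharing a surname block key (order-stable)."""
    pairs = _block_pairs(
        [normalized_key(r) for r in lic_list],
        [normalized_key(r) for r in nppes_list],
        _matching_config(config),
    )
    return [(lic_list[i], nppes_list[j]) for i, j in pairs]


def _block_pairs(
    lic_keys: Sequence[NormalizedEntityKey],
    nppes_keys: Sequence[NormalizedEntityKey],
    matching: MatchingConfig,
) -> list[tuple[int, int]]:
    depth = 2 if matching.fuzzy else 0
    index: dict[str, list[int]] = {}
    for j, key in enumerate(nppes_keys):
        for bk in _block_keys(key, depth):
            index.setdefault(bk, []).append(j)
    pairs: list[tuple[int, int]] = []
    for i, key in enumerate(lic_keys):
        hits: set[int] = set()
        for bk in _block_keys(key, depth):
            hits.update(index.get(bk, ()))
        pairs.extend((i, j) for j in sorted(hits))
    return pairs


# ---------------------------------------------------------------------------
# Multi-year matching
# ---------------------------------------------------------------------------

def match_all(
    lic_list: Sequence[LicensureRecord],
    nppes_snapshots: Mapping[int, Sequence[NPPESRecord]],
    config: RunConfig,
) -> list[MatchCandidate]:
    """Match every licensure record against every snapshot year.

    Per-entity agreement years accumulate per (license, NPI) pair; a year
    contributes to an entity only when the pair's surnames agree that year
    (the surname anchors the putative identity).  Each candidate carries
    its strongest match type over the window and the national record from
    its most recent matching year.
    """
    window = config.scoring.window
    missing = [y for y in window.years if y not in nppes_snapshots]
    if missing:
        raise ConfigurationError(f"no NPPES snapshot for window years {missing}")

    matching = config.matching
    order = matching.rank_order
    lic_keys = [normalized_key(r) for r in lic_list]

    # (lic index, npi) -> aggregation state
    agg: dict[tuple[int, str], MatchCandidate] = {}
    first_seen: dict[tuple[int, str], int] = {}

    for year in window.years:
        records = list(nppes_snapshots[year])
        nppes_keys = [normalized_key(r) for r in records]
        if matching.block:
            pairs: Iterable[tuple[int, int]] = _block_pairs(lic_keys, nppes_keys, matching)
        else:
            pairs = ((i, j) for i in range(len(lic_keys)) for j in range(len(nppes_keys)))
        for i, j in pairs:
            agree = _agreements(lic_keys[i], nppes_keys[j], matching.fuzzy)
            mtype = _type_from_agreements(agree, order)
            if mtype is MatchType.NONE:
                continue
            rec = records[j]
            key = (i, rec.npi)
            cand = agg.get(key)
            if cand is None:
                cand = MatchCandidate(
                    licensure=lic_list[i], nppes=rec, match_type=mtype,
                    entity_years={e: set() for e in ("last", "first", "city", "street")},
                )
                agg[key] = cand
                first_seen[key] = len(first_seen)
            else:
                if rank_of(mtype, matching) < rank_of(cand.match_type, matching):
                    cand.match_type = mtype
                cand.nppes = rec  # snapshots iterate oldest->newest
            cand.matched_years.add(year)
            for entity, ok in agree.items():
                if ok:
                    cand.entity_years[entity].add(year)

    ordered = sorted(agg.items(), key=lambda kv: (kv[0][0], first_seen[kv[0]]))
    return [cand for _, cand in ordered]


__all__ = [
    "MatchType", "MatchCandidate",
    "enumerate_match_types", "rank_of", "classify_match",
    "block_candidates", "match_all",
]
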