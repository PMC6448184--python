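"""Specialty-taxonomy filtering of national provider records.

Each supported provider type maps to a set of NUCC taxonomy codes, shipped
as an editable YAML table (``resources/taxonomy.yaml``).  National records
are kept for matching only if *either* their primary or their secondary
taxonomy code belongs to the set — secondary codes must be consulted
because providers with dual roles can carry the relevant taxonomy only in
the secondary slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigurationError
from .records_io import PROVIDER_TYPES, NPPESRecord, TaxonomyCode, is_valid_taxonomy


@dataclass(frozen=True)
class TaxonomySet:
    provider_type: str
    codes: frozenset[TaxonomyCode]

    @property
    def code_strings(self) -> frozenset[str]:
        return frozenset(c.code for c in self.codes)

    def __contains__(self, code: object) -> bool:
        if isinstance(code, TaxonomyCode):
            return code.code in self.code_strings
        return str(code).strip().upper() in self.code_strings


def _default_table_path() -> Path:
    return Path(str(resources.files("provlink").joinpath("resources/taxonomy.yaml")))


def load_taxonomy_table(path: str | Path | None = None) -> dict[str, TaxonomySet]:
    """Load the provider-type -> taxonomy-set table from YAML."""
    path = Path(path) if path is not None else _default_table_path()
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    table: dict[str, TaxonomySet] = {}
    for ptype, entries in raw.items():
        codes = []
        for code, label in entries.items():
            if not is_valid_taxonomy(code):
                raise ConfigurationError(f"malformed taxonomy code {code!r} for {ptype}")
            codes.append(TaxonomyCode(code=code, label=label or ""))
        if not codes:
            raise ConfigurationError(f"empty taxonomy set for provider type {ptype}")
        table[ptype] = TaxonomySet(provider_type=ptype, codes=frozenset(codes))
    return table


_CACHE: dict[Path, dict[str, TaxonomySet]] = {}


def taxonomy_set_for(provider_type: str, table_path: str | Path | None = None) -> TaxonomySet:
    """Return the configured taxonomy set for *provider_type*."""
    key = Path(table_path) if table_path is not None else _default_table_path()
    if key not in _CACHE:
        _CACHE[key] = load_taxonomy_table(key)
    table = _CACHE[key]
    if provider_type not in table:
        raise ConfigurationError(
            f"unsupported provider type {provider_type!r}; "
            f"supported: {', '.join(sorted(table))}"
        )
    return table[provider_type]


def filter_by_taxonomy(
    records: Sequence[NPPESRecord],
    provider_type: str,
    table_path: str | Path | None = None,
) -> list[NPPESRecord]:
    """Keep records whose primary OR secondary taxonomy is in the type's set.

    Order is preserved.  A record whose only in-scope code sits in the
    secondary slot is kept (dual-role providers); a record whose codes are
    both out of scope is excluded even if it denotes the same person.
    """
    tset = taxonomy_set_for(provider_type, table_path)
    kept = []
    for rec in records:
        if rec.taxonomy_primary in tset:
            kept.append(rec)
        elif rec.taxonomy_secondary is not None and rec.taxonomy_secondary in tset:
            kept.append(rec)
    return kept


def assert_default_sets_disjoint(table: dict[str, TaxonomySet] | None = None) -> None:
    """Raise ConfigurationError if any two provider-type sets overlap."""
    table = table if table is not None else load_taxonomy_table()
    types = list(table)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            overlap = table[a].code_strings & table[b].code_strings
            if overlap:
                raise ConfigurationError(
                    f"taxonomy sets for {a} and {b} overlap: {sorted(overlap)}"
                )


__all__ = [
    "TaxonomySet", "load_taxonomy_table", "taxonomy_set_for",
    "filter_by_taxonomy", "assert_default_sets_disjoint", "PROVIDER_TYPES",
]
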