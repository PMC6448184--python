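"""Synthetic paired licensure/national cohorts with ground truth.

The generator produces ``n`` base identities, each present in a state
roster and (unless deliberately withheld) in every yearly national
snapshot, then injects the qualitative error channels observed in real
linkage work:

* ``misspelling``   — a 1–2 character edit in a first or last name on one
  side ("Helen"/"Hellan" style);
* ``name_change``   — the surname is replaced from a staged year onward
  (marriage/divorce style), or a token is inserted into a compound surname;
* ``moved``         — a wholly different street + city on the national side
  from a staged year onward, so temporal scoring is exercised;
* ``bad_taxonomy``  — the primary taxonomy is replaced with an out-of-set
  code and the secondary emptied (the record then dies at the taxonomy
  filter);
* ``middle_as_first`` — the national first name is the provider's middle
  name;
* ``unmatched_licensure`` — the provider has no national row at all
  (deceased/retired roster residue).

Channels are mutually exclusive per identity.  Generation is fully
deterministic: one master seed, with per-identity substreams derived from
``(seed, identity index)`` so earlier identities are unaffected by ``n``.

Name/address lexicons are small bundled word lists; the generator targets
structural realism (formats, error channels), not demographic realism.
Full names and (city, street) pairs are unique across a cohort by
construction, which makes the noise-free cohort perfectly linkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .records_io import (
    LicensureRecord,
    NPPESRecord,
    PostalAddress,
    ProviderName,
    TaxonomyCode,
    npi_check_digit,
    write_licensure_list,
    write_nppes_puf,
)
from .taxonomy_filter import taxonomy_set_for
from .temporal_scoring import DEFAULT_WINDOW, ScoringWindow

ERROR_CHANNELS: tuple[str, ...] = (
    "misspelling", "name_change", "moved", "bad_taxonomy",
    "middle_as_first", "unmatched_licensure",
)

#: taxonomy codes outside every supported provider-type set
DECOY_TAXONOMIES: tuple[str, ...] = (
    "204E00000X",  # oral & maxillofacial surgery (physician family)
    "104100000X",  # social worker
    "163W00000X",  # registered nurse
    "207Q00000X",  # family medicine physician
    "152W00000X",  # optometrist
)

_NEIGHBOR_STATES = ("MA", "NY", "RI", "FL")
_FAR_STATES = ("NJ", "NH", "VT", "PA", "CA")

_STREET_SUFFIX_PAIRS = (
    ("Avenue", "Ave"), ("Street", "St"), ("Road", "Rd"), ("Lane", "Ln"),
    ("Drive", "Dr"), ("Court", "Ct"), ("Terrace", "Ter"), ("Boulevard", "Blvd"),
)

_DISTRACTOR_FRACTION = 0.15


def _lexicon(name: str) -> tuple[str, ...]:
    text = resources.files("provlink").joinpath(f"resources/lexicons/{name}").read_text("utf-8")
    return tuple(line.strip() for line in text.splitlines() if line.strip())


_FIRST = _lexicon("first_names.txt")
_LAST = _lexicon("last_names.txt")
_STREETS = _lexicon("street_names.txt")
_CITIES = _lexicon("cities.txt")


# ---------------------------------------------------------------------------
# Configuration & truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorConfig:
    p_misspelling: float = 0.0
    p_name_change: float = 0.0
    p_moved: float = 0.0
    p_bad_taxonomy: float = 0.0
    p_middle_as_first: float = 0.0
    p_unmatched_licensure: float = 0.0

    def probabilities(self) -> dict[str, float]:
        return {
            "misspelling": self.p_misspelling,
            "name_change": self.p_name_change,
            "moved": self.p_moved,
            "bad_taxonomy": self.p_bad_taxonomy,
            "middle_as_first": self.p_middle_as_first,
            "unmatched_licensure": self.p_unmatched_licensure,
        }

    def validate(self) -> None:
        probs = self.probabilities()
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"p_{name}={p} outside [0, 1]")
        if sum(probs.values()) > 1.0 + 1e-12:
            raise ConfigurationError("error-channel probabilities sum to more than 1")


@dataclass(frozen=True)
class GroundTruthLink:
    license_number: str
    npi: str | None
    error_labels: frozenset[str]
    details: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.npi is None) != ("unmatched_licensure" in self.error_labels):
            raise ValueError("npi must be None exactly for the unmatched channel")


@dataclass(frozen=True)
class _Street:
    number: int
    name: str
    suffix_full: str
    suffix_abbr: str

    def render(self, abbreviated: bool) -> str:
        suffix = self.suffix_abbr if abbreviated else self.suffix_full
        return f"{self.number} {self.name} {suffix}"


@dataclass
class Identity:
    """One synthetic provider with roster-side and national-side views."""

    index: int
    first: str
    middle: str
    last: str
    license_number: str
    npi: str
    gender: str
    phone: str
    city: str
    street: _Street
    state: str
    zip: str
    taxonomy_primary: str
    taxonomy_secondary: str
    lic_street_abbrev: bool
    npp_street_abbrev: bool
    channel: str = "none"
    details: dict = field(default_factory=dict)
    # side-specific overrides installed by inject_error
    lic_first: str | None = None
    lic_last: str | None = None
    npp_first: str | None = None
    npp_last: str | None = None          # applies from details["change_year"] if set
    npp_street: _Street | None = None    # applies from details["move_year"] if set
    npp_city: str | None = None
    npp_taxonomy: str | None = None

    # -- views -------------------------------------------------------------

    def licensure_record(self, provider_type: str, year: int) -> LicensureRecord:
        return LicensureRecord(
            license_number=self.license_number,
            provider_type=provider_type,
            name=ProviderName(first=self.lic_first or self.first, last=self.lic_last or self.last),
            address=PostalAddress(
                street=self.street.render(self.lic_street_abbrev),
                city=self.city, state=self.state, zip=self.zip,
            ),
            year=year,
        )

    def nppes_record(self, year: int) -> NPPESRecord | None:
        if self.channel == "unmatched_licensure":
            return None
        first = self.npp_first or self.first
        last = self.last
        if self.npp_last is not None:
            change_year = self.details.get("change_year")
            if change_year is None or year >= change_year:
                last = self.npp_last
        city, street = self.city, self.street
        if self.npp_street is not None and year >= self.details["move_year"]:
            city, street = self.npp_city, self.npp_street
        tax1 = self.npp_taxonomy or self.taxonomy_primary
        tax2 = "" if self.npp_taxonomy else self.taxonomy_secondary
        addr = PostalAddress(
            street=street.render(self.npp_street_abbrev),
            city=city, state=self.state, zip=self.zip,
        )
        return NPPESRecord(
            npi=self.npi,
            name=ProviderName(first=first, middle=self.middle, last=last),
            gender=self.gender,
            phone=self.phone,
            taxonomy_primary=TaxonomyCode(tax1),
            taxonomy_secondary=TaxonomyCode(tax2) if tax2 else None,
            mailing_address=addr,
            practice_address=addr,
            other_identifiers=(("CT", self.license_number),),
            year=year,
        )


@dataclass
class Cohort:
    licensure: list[LicensureRecord]
    nppes: dict[int, list[NPPESRecord]]
    truth: list[GroundTruthLink]
    identities: list[Identity]
    manifest: dict
    paths: dict[str, Path] | None = None


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def _mutate_name(name: str, rng: np.random.Generator, n_edits: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = name
    for _ in range(n_edits):
        ops = ["substitute", "insert", "double"]
        if len(out) > 3:
            ops.append("delete")
        op = ops[int(rng.integers(len(ops)))]
        if op == "substitute":
            i = int(rng.integers(1, len(out)))
            repl = letters[int(rng.integers(26))]
            while repl == out[i].lower():
                repl = letters[int(rng.integers(26))]
            out = out[:i] + repl + out[i + 1:]
        elif op == "insert":
            i = int(rng.integers(1, len(out) + 1))
            out = out[:i] + letters[int(rng.integers(26))] + out[i:]
        elif op == "double":
            i = int(rng.integers(1, len(out)))
            out = out[:i] + out[i] + out[i:]
        else:  # delete
            i = int(rng.integers(1, len(out)))
            out = out[:i] + out[i + 1:]
    return out


def inject_error(identity: Identity, channel: str, rng: np.random.Generator) -> tuple[Identity, str]:
    """Apply one error channel to an identity; returns (mutated, label)."""
    ident = replace(identity, details=dict(identity.details))
    ident.channel = channel
    if channel == "misspelling":
        side = "licensure" if rng.random() < 0.5 else "nppes"
        fld = "first" if rng.random() < 0.5 else "last"
        original = getattr(ident, fld)
        n_edits = 1 if len(original) < 6 else int(rng.integers(1, 3))
        mutated = _mutate_name(original, rng, n_edits)
        while mutated.upper() == original.upper():
            mutated = _mutate_name(original, rng, max(1, n_edits))
        if side == "licensure":
            setattr(ident, f"lic_{fld}", mutated)
        else:
            setattr(ident, f"npp_{fld}", mutated)
        ident.details.update(side=side, field=fld, original=original, mutated=mutated)
    elif channel == "name_change":
        style = "replace" if rng.random() < 0.6 else "insert_token"
        new_token = ident.last
        while new_token == ident.last:
            new_token = _LAST[int(rng.integers(len(_LAST)))]
        if style == "replace":
            change_year = int(rng.choice(ident.details["window_years"]))
            ident.npp_last = new_token
            ident.details.update(style=style, change_year=change_year, new_last=new_token)
        else:
            ident.npp_last = f"{ident.last} {new_token}"
            ident.details.update(style=style, new_last=ident.npp_last)
    elif channel == "moved":
        move_year = int(rng.choice(ident.details["window_years"]))
        new_city = ident.city
        while new_city == ident.city:
            new_city = _CITIES[int(rng.integers(len(_CITIES)))]
        suffix = _STREET_SUFFIX_PAIRS[int(rng.integers(len(_STREET_SUFFIX_PAIRS)))]
        new_street = _Street(
            number=int(rng.integers(1, 10000)),
            name=_STREETS[int(rng.integers(len(_STREETS)))],
            suffix_full=suffix[0], suffix_abbr=suffix[1],
        )
        while new_street.name == ident.street.name:
            new_street = replace(new_street, name=_STREETS[int(rng.integers(len(_STREETS)))])
        ident.npp_city = new_city
        ident.npp_street = new_street
        ident.details.update(move_year=move_year)
    elif channel == "bad_taxonomy":
        ident.npp_taxonomy = DECOY_TAXONOMIES[int(rng.integers(len(DECOY_TAXONOMIES)))]
        ident.details.update(decoy=ident.npp_taxonomy)
    elif channel == "middle_as_first":
        ident.npp_first = ident.middle
    elif channel == "unmatched_licensure":
        pass  # nppes_record() returns None for this channel
    else:
        raise ConfigurationError(f"unknown error channel {channel!r}")
    return ident, channel


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _pick_channel(u: float, errors: ErrorConfig) -> str:
    cum = 0.0
    for channel, p in errors.probabilities().items():
        cum += p
        if u < cum:
            return channel
    return "none"


def _draw_identity(
    i: int,
    rng: np.random.Generator,
    codes: Sequence[str],
    used_fullnames: set[tuple[str, str]],
    used_addresses: set[tuple[str, int, str]],
    used_npis: set[str],
) -> Identity:
    first = _FIRST[int(rng.integers(len(_FIRST)))]
    last = _LAST[int(rng.integers(len(_LAST)))]
    while (first.upper(), last.upper()) in used_fullnames:
        first = _FIRST[int(rng.integers(len(_FIRST)))]
        last = _LAST[int(rng.integers(len(_LAST)))]
    used_fullnames.add((first.upper(), last.upper()))
    middle = first
    while middle == first:
        middle = _FIRST[int(rng.integers(len(_FIRST)))]

    city = _CITIES[int(rng.integers(len(_CITIES)))]
    suffix = _STREET_SUFFIX_PAIRS[int(rng.integers(len(_STREET_SUFFIX_PAIRS)))]
    street = _Street(
        number=int(rng.integers(1, 10000)),
        name=_STREETS[int(rng.integers(len(_STREETS)))],
        suffix_full=suffix[0], suffix_abbr=suffix[1],
    )
    while (city, street.number, street.name) in used_addresses:
        street = replace(street, number=int(rng.integers(1, 10000)))
    used_addresses.add((city, street.number, street.name))

    base9 = "1" + "".join(str(int(d)) for d in rng.integers(0, 10, size=8))
    npi = base9 + str(npi_check_digit(base9))
    while npi in used_npis:
        base9 = "1" + "".join(str(int(d)) for d in rng.integers(0, 10, size=8))
        npi = base9 + str(npi_check_digit(base9))
    used_npis.add(npi)

    state = "CT" if rng.random() < 0.9 else _NEIGHBOR_STATES[int(rng.integers(len(_NEIGHBOR_STATES)))]
    return Identity(
        index=i,
        first=first, middle=middle, last=last,
        license_number=f"{i + 1:06d}",
        npi=npi,
        gender="F" if rng.random() < 0.5 else "M",
        phone="860" + "".join(str(int(d)) for d in rng.integers(0, 10, size=7)),
        city=city, street=street, state=state,
        zip="06" + "".join(str(int(d)) for d in rng.integers(0, 10, size=3)),
        taxonomy_primary=codes[int(rng.integers(len(codes)))],
        taxonomy_secondary=(codes[int(rng.integers(len(codes)))] if rng.random() < 0.15 else ""),
        lic_street_abbrev=bool(rng.random() < 0.5),
        npp_street_abbrev=bool(rng.random() < 0.5),
    )


def generate_cohort(
    n: int,
    provider_type: str = "certified_nurse_midwife",
    window: ScoringWindow = DEFAULT_WINDOW,
    errors: ErrorConfig = ErrorConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a paired cohort; optionally write the file set to *out_dir*.

    Files written: ``licensure.csv``, one ``nppes_<year>.csv`` per window
    year, ``truth.tsv`` and ``manifest.json``.
    """
    if n < 1:
        raise ConfigurationError(f"cohort size must be >= 1, got {n}")
    errors.validate()
    tset = taxonomy_set_for(provider_type)
    codes = sorted(tset.code_strings)

    used_fullnames: set[tuple[str, str]] = set()
    used_addresses: set[tuple[str, int, str]] = set()
    used_npis: set[str] = set()

    identities: list[Identity] = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        ident = _draw_identity(i, rng, codes, used_fullnames, used_addresses, used_npis)
        ident.details["window_years"] = list(window.years)
        channel = _pick_channel(float(rng.random()), errors)
        if channel != "none":
            ident, _ = inject_error(ident, channel, rng)
        identities.append(ident)

    # national-only distractors: never in the roster, exercise both filters
    n_distract = round(_DISTRACTOR_FRACTION * n)
    distractors: list[Identity] = []
    for d in range(n_distract):
        rng = np.random.default_rng([seed, n + d])
        ident = _draw_identity(n + d, rng, codes, used_fullnames, used_addresses, used_npis)
        kind = rng.random()
        if kind < 0.4:
            ident.npp_taxonomy = DECOY_TAXONOMIES[int(rng.integers(len(DECOY_TAXONOMIES)))]
        elif kind < 0.65:
            ident.state = _FAR_STATES[int(rng.integers(len(_FAR_STATES)))]
        distractors.append(ident)

    lic_year = window.end_year
    licensure = [ident.licensure_record(provider_type, lic_year) for ident in identities]
    nppes: dict[int, list[NPPESRecord]] = {}
    for year in window.years:
        rows = [ident.nppes_record(year) for ident in identities + distractors]
        nppes[year] = [r for r in rows if r is not None]

    truth = [
        GroundTruthLink(
            license_number=ident.license_number,
            npi=None if ident.channel == "unmatched_licensure" else ident.npi,
            error_labels=frozenset({ident.channel if ident.channel != "none" else "none"}),
            details={k: v for k, v in ident.details.items() if k != "window_years"},
        )
        for ident in identities
    ]

    manifest = {
        "n": n,
        "n_distractors": n_distract,
        "provider_type": provider_type,
        "window": {"start": window.start_year, "end": window.end_year},
        "errors": errors.probabilities(),
        "seed": seed,
    }

    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"licensure": out_dir / "licensure.csv", "truth": out_dir / "truth.tsv"}
        write_licensure_list(licensure, paths["licensure"])
        for year in window.years:
            p = out_dir / f"nppes_{year}.csv"
            write_nppes_puf(nppes[year], p)
            paths[f"nppes_{year}"] = p
        write_truth_table(truth, paths["truth"])
        manifest["files"] = {k: str(v) for k, v in paths.items()}
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        paths["manifest"] = manifest_path

    return Cohort(
        licensure=licensure, nppes=nppes, truth=truth,
        identities=identities, manifest=manifest, paths=paths,
    )


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

def write_truth_table(truth: Sequence[GroundTruthLink], path: str | Path) -> int:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("license_number\tnpi\terror_labels\n")
        for link in truth:
            labels = ";".join(sorted(link.error_labels))
            fh.write(f"{link.license_number}\t{link.npi or ''}\t{labels}\n")
    return len(truth)


def read_truth_table(path: str | Path) -> list[GroundTruthLink]:
    from .errors import InputError

    out = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["license_number", "npi", "error_labels"]:
            raise InputError(f"unexpected truth-table header in {path}: {header}")
        for line in fh:
            lic, npi, labels = line.rstrip("\n").split("\t")
            out.append(GroundTruthLink(
                license_number=lic,
                npi=npi or None,
                error_labels=frozenset(labels.split(";")) if labels else frozenset({"none"}),
            ))
    return out


__all__ = [
    "ERROR_CHANNELS", "DECOY_TAXONOMIES",
    "ErrorConfig", "GroundTruthLink", "Identity", "Cohort",
    "inject_error", "generate_cohort", "write_truth_table", "read_truth_table",
]
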