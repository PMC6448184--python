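"""Candidate resolution, record merging, and the end-to-end pipeline.

The update stage turns scored candidates into one clean directory row per
licensed provider: per license the best-scoring candidate wins (ties broken
by match-type rank, then most recent snapshot year; exact ties are
*excluded* and reported as ambiguous rather than guessed), and linkage is
one-to-one globally — an NPI claimed by a higher-scoring license is out of
contention for all others.

``build_directory`` runs the whole pipeline (read -> taxonomy filter ->
location filter -> match -> score -> threshold -> resolve -> merge ->
write) and reports record counts at every stage; every stage conserves
``in == out + dropped``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import records_io
from .config import RunConfig
from .entity_normalization import filter_by_location
from .errors import MergeError, ProvlinkError
from .matching_engine import MatchCandidate, MatchType, match_all, rank_of
from .records_io import (
    LicensureRecord,
    NPPESRecord,
    PostalAddress,
    ProviderName,
    TaxonomyCode,
    validate_npi,
)
from .taxonomy_filter import filter_by_taxonomy, taxonomy_set_for
from .temporal_scoring import apply_threshold, score_candidate


@dataclass(frozen=True)
class LinkedProviderRecord:
    """One merged output row: national fields keyed by the state license."""

    legal_name: ProviderName
    npi: str
    gender: str
    phone: str
    taxonomy: TaxonomyCode
    practice_address: PostalAddress
    mailing_address: PostalAddress
    other_identifiers: tuple[tuple[str, str], ...]
    license_number: str
    match_type: MatchType
    total_score: int


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    reasons: dict[str, int] = field(default_factory=dict)
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_out

    def to_dict(self) -> dict:
        return {
            "stage": self.stage, "in": self.n_in, "out": self.n_out,
            "dropped": self.n_dropped, "reasons": self.reasons,
            "dropped_ids": self.dropped_ids,
        }


@dataclass
class RunReport:
    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: StageReport) -> None:
        self.stages.append(stage)

    def stage(self, name: str) -> StageReport:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for s in self.stages:
                fh.write(json.dumps(s.to_dict()) + "\n")

    def to_text(self) -> str:
        lines = [f"{'stage':<18}{'in':>8}{'out':>8}{'dropped':>8}"]
        for s in self.stages:
            lines.append(f"{s.stage:<18}{s.n_in:>8}{s.n_out:>8}{s.n_dropped:>8}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

def _sort_key(cand: MatchCandidate, config: RunConfig):
    return (-cand.total, rank_of(cand.match_type, config.matching), -cand.recent_year)


def resolve_candidates(
    accepted: Sequence[MatchCandidate],
    config: RunConfig | None = None,
) -> tuple[list[MatchCandidate], list[MatchCandidate], list[MatchCandidate]]:
    """Pick one winner per license, one-to-one in NPI.

    Returns ``(winners, ambiguous, contended)``: *ambiguous* candidates tied
    exactly on (total, match-type rank, recent year) for the same license
    and were excluded; *contended* licenses lost every viable NPI to a
    higher-scoring license.
    """
    config = config or RunConfig()
    by_license: dict[str, list[MatchCandidate]] = {}
    for cand in accepted:
        by_license.setdefault(cand.licensure.license_number, []).append(cand)

    ambiguous: list[MatchCandidate] = []
    ranked: dict[str, list[MatchCandidate]] = {}
    for lic, cands in by_license.items():
        cands = sorted(cands, key=lambda c: _sort_key(c, config))
        best_key = _sort_key(cands[0], config)
        tied = [c for c in cands if _sort_key(c, config) == best_key]
        if len(tied) > 1 and len({c.nppes.npi for c in tied}) > 1:
            ambiguous.extend(tied)
            continue
        ranked[lic] = cands

    # global one-to-one: strongest winners claim NPIs first
    order = sorted(ranked, key=lambda lic: (_sort_key(ranked[lic][0], config), lic))
    winners: list[MatchCandidate] = []
    contended: list[MatchCandidate] = []
    used_npis: set[str] = set()
    for lic in order:
        chosen = None
        for cand in ranked[lic]:
            if cand.nppes.npi not in used_npis:
                chosen = cand
                break
        if chosen is None:
            contended.append(ranked[lic][0])
            continue
        used_npis.add(chosen.nppes.npi)
        winners.append(chosen)
    return winners, ambiguous, contended


def merge_record(
    lic: LicensureRecord,
    rec: NPPESRecord,
    candidate: MatchCandidate,
) -> LinkedProviderRecord:
    """Merge a resolved pair: national record supplies identity fields, the
    roster supplies the license number; provenance columns carried through.

    The national file is the legal-name source — when a roster still lists
    a pre-marriage surname the national name wins.
    """
    if not validate_npi(rec.npi):
        raise MergeError(f"invalid NPI {rec.npi!r} for license {lic.license_number!r}")
    if not lic.license_number:
        raise MergeError("empty license number")
    taxonomy = rec.taxonomy_primary
    tset = taxonomy_set_for(lic.provider_type)
    if taxonomy not in tset and rec.taxonomy_secondary is not None and rec.taxonomy_secondary in tset:
        taxonomy = rec.taxonomy_secondary
    return LinkedProviderRecord(
        legal_name=rec.name,
        npi=rec.npi,
        gender=rec.gender,
        phone=rec.phone,
        taxonomy=taxonomy,
        practice_address=rec.practice_address,
        mailing_address=rec.mailing_address,
        other_identifiers=rec.other_identifiers,
        license_number=lic.license_number,
        match_type=candidate.match_type,
        total_score=candidate.total,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class BuildResult:
    output_path: Path
    report: RunReport
    records: list[LinkedProviderRecord]
    ambiguous: list[MatchCandidate]


def build_directory(
    lic_path: str | Path,
    nppes_paths: Mapping[int, str | Path],
    provider_type: str,
    config: RunConfig,
    out_dir: str | Path,
) -> BuildResult:
    """Run the full linkage pipeline and write the output directory CSV.

    Also writes ``run_report.jsonl``, ``rejects.csv`` (quarantined national
    rows), ``ambiguous.csv`` and the effective config next to the output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    try:
        lic_result = records_io.read_licensure_list(
            lic_path, provider_type, config.scoring.window.end_year,
            column_map=config.licensure_columns,
        )
    except ProvlinkError as exc:
        raise type(exc)(f"[stage read_licensure] {exc}") from exc
    report.add(StageReport(
        stage="read_licensure", n_in=lic_result.n_rows, n_out=len(lic_result.records),
        reasons={
            "empty_last_name": lic_result.dropped_empty_last,
            "duplicate_license": len(lic_result.duplicate_licenses),
        },
    ))

    snapshots: dict[int, list[NPPESRecord]] = {}
    quarantined = []
    n_rows = 0
    for year, path in sorted(nppes_paths.items()):
        try:
            res = records_io.read_nppes_puf(path, int(year))
        except ProvlinkError as exc:
            raise type(exc)(f"[stage read_nppes] {exc}") from exc
        snapshots[int(year)] = res.records
        quarantined.extend(res.quarantined)
        n_rows += res.n_rows
    report.add(StageReport(
        stage="read_nppes", n_in=n_rows,
        n_out=sum(len(v) for v in snapshots.values()),
        reasons={"quarantined": len(quarantined)},
    ))
    records_io.write_quarantine(quarantined, out_dir / "rejects.csv")

    tax_dropped: list[str] = []
    loc_dropped: list[str] = []
    n_tax_in = n_tax_out = n_loc_out = 0
    for year in list(snapshots):
        recs = snapshots[year]
        n_tax_in += len(recs)
        kept = filter_by_taxonomy(recs, provider_type, config.taxonomy_table)
        kept_set = {id(r) for r in kept}
        tax_dropped.extend(r.npi for r in recs if id(r) not in kept_set)
        n_tax_out += len(kept)
        located = filter_by_location(kept, config.states)
        located_set = {id(r) for r in located}
        loc_dropped.extend(r.npi for r in kept if id(r) not in located_set)
        n_loc_out += len(located)
        snapshots[year] = located
    report.add(StageReport(
        stage="taxonomy_filter", n_in=n_tax_in, n_out=n_tax_out,
        reasons={"taxonomy_out_of_set": n_tax_in - n_tax_out},
        dropped_ids=sorted(set(tax_dropped)),
    ))
    report.add(StageReport(
        stage="location_filter", n_in=n_tax_out, n_out=n_loc_out,
        reasons={"state_out_of_set": n_tax_out - n_loc_out},
        dropped_ids=sorted(set(loc_dropped)),
    ))

    lic_records = lic_result.records
    candidates = match_all(lic_records, snapshots, config)
    matched_licenses = {c.licensure.license_number for c in candidates}
    report.add(StageReport(
        stage="match", n_in=len(lic_records), n_out=len(matched_licenses),
        reasons={"no_candidate": len(lic_records) - len(matched_licenses)},
        dropped_ids=sorted(
            r.license_number for r in lic_records
            if r.license_number not in matched_licenses
        ),
    ))

    window = config.scoring.window
    for cand in candidates:
        score_candidate(cand, window)
    accepted = apply_threshold(candidates, config.scoring.threshold)
    report.add(StageReport(
        stage="threshold", n_in=len(candidates), n_out=len(accepted),
        reasons={"below_threshold": len(candidates) - len(accepted)},
    ))

    winners, ambiguous, contended = resolve_candidates(accepted, config)
    n_resolve_in = len({c.licensure.license_number for c in accepted})
    report.add(StageReport(
        stage="resolve", n_in=n_resolve_in, n_out=len(winners),
        reasons={
            "ambiguous_tie": len({c.licensure.license_number for c in ambiguous}),
            "npi_contended": len(contended),
        },
        dropped_ids=sorted({c.licensure.license_number for c in ambiguous}),
    ))
    _write_ambiguous(ambiguous, out_dir / "ambiguous.csv")

    merged: list[LinkedProviderRecord] = []
    merge_rejects = 0
    for cand in sorted(winners, key=lambda c: c.licensure.license_number):
        try:
            merged.append(merge_record(cand.licensure, cand.nppes, cand))
        except MergeError:
            merge_rejects += 1
    report.add(StageReport(
        stage="merge", n_in=len(winners), n_out=len(merged),
        reasons={"invariant_violation": merge_rejects},
    ))

    output_path = out_dir / "directory.csv"
    n_written = records_io.write_directory(merged, output_path)
    report.add(StageReport(stage="write", n_in=len(merged), n_out=n_written))

    report.write_jsonl(out_dir / "run_report.jsonl")
    config.write(out_dir / "effective_config.json")
    return BuildResult(output_path=output_path, report=report, records=merged, ambiguous=ambiguous)


def _write_ambiguous(ambiguous: Sequence[MatchCandidate], path: Path) -> None:
    import csv

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["license_number", "npi", "match_type", "total_score", "recent_year"])
        for cand in ambiguous:
            writer.writerow([
                cand.licensure.license_number, cand.nppes.npi,
                cand.match_type.name, cand.total, cand.recent_year,
            ])


__all__ = [
    "LinkedProviderRecord", "StageReport", "RunReport", "BuildResult",
    "resolve_candidates", "merge_record", "build_directory",
]
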