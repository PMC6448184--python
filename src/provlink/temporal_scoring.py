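"""Temporal point scoring of match candidates.

Each of the four scored entities (last name, first name, city, street)
earns 5 points when it agrees in the most recent snapshot year of the
window, losing one point per year that the most recent agreeing year
recedes from the window end, floored at zero.  The four entity scores sum
to the candidate total (0–20), which is compared against an acceptance
threshold.

The default threshold of 12 is this package's choice, NOT a published
value: it accepts a recent full-name match with at least one corroborating
address entity and rejects any single-entity coincidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from .errors import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from .matching_engine import MatchCandidate

SCORED_ENTITIES: tuple[str, ...] = ("last", "first", "city", "street")

MAX_ENTITY_SCORE = 5
MAX_TOTAL_SCORE = MAX_ENTITY_SCORE * len(SCORED_ENTITIES)

DEFAULT_THRESHOLD = 12


@dataclass(frozen=True)
class ScoringWindow:
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigurationError(
                f"scoring window end {self.end_year} precedes start {self.start_year}"
            )

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.end_year + 1))

    def __contains__(self, year: object) -> bool:
        return isinstance(year, int) and self.start_year <= year <= self.end_year


DEFAULT_WINDOW = ScoringWindow(2013, 2017)


@dataclass(frozen=True)
class EntityScoreVector:
    last: int
    first: int
    city: int
    street: int
    total: int = field(default=-1)

    def __post_init__(self) -> None:
        for name in SCORED_ENTITIES:
            v = getattr(self, name)
            if not 0 <= v <= MAX_ENTITY_SCORE:
                raise ValueError(f"entity score {name}={v} outside [0, {MAX_ENTITY_SCORE}]")
        computed = self.last + self.first + self.city + self.street
        if self.total == -1:
            object.__setattr__(self, "total", computed)
        elif self.total != computed:
            raise ValueError(f"total {self.total} != component sum {computed}")


def score_entity(match_years: Iterable[int], window: ScoringWindow) -> int:
    """Points for one entity given the snapshot years it agreed in.

    5 points for agreement in the window's most recent year, one point off
    per year earlier, floored at 0; no agreement at all scores 0.
    """
    years = set(match_years)
    if not years:
        return 0
    outside = years - set(window.years)
    if outside:
        raise ValueError(f"match years {sorted(outside)} outside window {window}")
    return max(0, MAX_ENTITY_SCORE - (window.end_year - max(years)))


def score_candidate(candidate: "MatchCandidate", window: ScoringWindow) -> EntityScoreVector:
    """Score each of the four entities independently and set the total."""
    vec = EntityScoreVector(
        last=score_entity(candidate.entity_years.get("last", ()), window),
        first=score_entity(candidate.entity_years.get("first", ()), window),
        city=score_entity(candidate.entity_years.get("city", ()), window),
        street=score_entity(candidate.entity_years.get("street", ()), window),
    )
    candidate.scores = vec
    candidate.total = vec.total
    return vec


def apply_threshold(candidates: Sequence["MatchCandidate"], threshold: int) -> list["MatchCandidate"]:
    """Keep scored candidates with ``total >= threshold`` (stable order)."""
    if not 0 <= threshold <= MAX_TOTAL_SCORE:
        raise ConfigurationError(f"threshold {threshold} outside [0, {MAX_TOTAL_SCORE}]")
    return [c for c in candidates if c.total >= threshold]


__all__ = [
    "SCORED_ENTITIES", "MAX_ENTITY_SCORE", "MAX_TOTAL_SCORE", "DEFAULT_THRESHOLD",
    "ScoringWindow", "DEFAULT_WINDOW", "EntityScoreVector",
    "score_entity", "score_candidate", "apply_threshold",
]
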