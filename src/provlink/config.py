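"""Run configuration: defaults, YAML loading, and serialization.

Every pipeline run persists its effective configuration beside its outputs
so runs are auditable and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .entity_normalization import DEFAULT_STATES
from .errors import ConfigurationError
from .records_io import PROVIDER_TYPES
from .temporal_scoring import (
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW,
    MAX_TOTAL_SCORE,
    ScoringWindow,
)

DEFAULT_RANK_ORDER: tuple[str, ...] = (
    "FL_CS", "FL_C", "FL_S", "FL", "L_CS", "L_C", "L_S",
)


@dataclass(frozen=True)
class MatchingConfig:
    #: exact comparison by default; fuzzy tolerates misspelling-class edits
    fuzzy: bool = False
    block: bool = True
    rank_order: tuple[str, ...] = DEFAULT_RANK_ORDER

    def __post_init__(self) -> None:
        if sorted(self.rank_order) != sorted(DEFAULT_RANK_ORDER):
            raise ConfigurationError(
                f"rank_order must be a permutation of {DEFAULT_RANK_ORDER}, "
                f"got {self.rank_order}"
            )


@dataclass(frozen=True)
class ScoringConfig:
    window: ScoringWindow = DEFAULT_WINDOW
    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= MAX_TOTAL_SCORE:
            raise ConfigurationError(
                f"scoring.threshold {self.threshold} outside [0, {MAX_TOTAL_SCORE}]"
            )


@dataclass(frozen=True)
class RunConfig:
    provider_type: str = "certified_nurse_midwife"
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    states: frozenset[str] = DEFAULT_STATES
    seed: int | None = None
    licensure_columns: Mapping[str, str] | None = None
    taxonomy_table: str | None = None

    def __post_init__(self) -> None:
        if self.provider_type not in PROVIDER_TYPES:
            raise ConfigurationError(
                f"unknown provider_type {self.provider_type!r}; "
                f"supported: {', '.join(PROVIDER_TYPES)}"
            )
        if not self.states:
            raise ConfigurationError("states must be non-empty")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "provider_type": self.provider_type,
            "matching": {
                "fuzzy": self.matching.fuzzy,
                "block": self.matching.block,
                "rank_order": list(self.matching.rank_order),
            },
            "scoring": {
                "window": {
                    "start": self.scoring.window.start_year,
                    "end": self.scoring.window.end_year,
                },
                "threshold": self.scoring.threshold,
            },
            "states": sorted(self.states),
            "seed": self.seed,
            "licensure_columns": dict(self.licensure_columns) if self.licensure_columns else None,
            "taxonomy_table": self.taxonomy_table,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        try:
            matching = d.get("matching", {}) or {}
            scoring = d.get("scoring", {}) or {}
            window = scoring.get("window", {}) or {}
            return cls(
                provider_type=d.get("provider_type", "certified_nurse_midwife"),
                matching=MatchingConfig(
                    fuzzy=bool(matching.get("fuzzy", False)),
                    block=bool(matching.get("block", True)),
                    rank_order=tuple(matching.get("rank_order", DEFAULT_RANK_ORDER)),
                ),
                scoring=ScoringConfig(
                    window=ScoringWindow(
                        int(window.get("start", DEFAULT_WINDOW.start_year)),
                        int(window.get("end", DEFAULT_WINDOW.end_year)),
                    ),
                    threshold=int(scoring.get("threshold", DEFAULT_THRESHOLD)),
                ),
                states=frozenset(d.get("states", DEFAULT_STATES)),
                seed=d.get("seed"),
                licensure_columns=d.get("licensure_columns"),
                taxonomy_table=d.get("taxonomy_table"),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid configuration: {exc}") from exc

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Overrides use the flattened keys ``provider_type``, ``fuzzy``, ``block``,
    ``threshold``, ``window_start``, ``window_end``, ``states``, ``seed``.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    cfg = RunConfig.from_dict(data)
    if not overrides:
        return cfg
    matching = cfg.matching
    scoring = cfg.scoring
    if "fuzzy" in overrides and overrides["fuzzy"] is not None:
        matching = replace(matching, fuzzy=bool(overrides["fuzzy"]))
    if "block" in overrides and overrides["block"] is not None:
        matching = replace(matching, block=bool(overrides["block"]))
    window = scoring.window
    if overrides.get("window_start") is not None or overrides.get("window_end") is not None:
        window = ScoringWindow(
            int(overrides.get("window_start") or window.start_year),
            int(overrides.get("window_end") or window.end_year),
        )
    threshold = scoring.threshold
    if overrides.get("threshold") is not None:
        threshold = int(overrides["threshold"])
    scoring = ScoringConfig(window=window, threshold=threshold)
    kwargs: dict[str, Any] = {"matching": matching, "scoring": scoring}
    if overrides.get("provider_type") is not None:
        kwargs["provider_type"] = overrides["provider_type"]
    if overrides.get("states") is not None:
        kwargs["states"] = frozenset(overrides["states"])
    if overrides.get("seed") is not None:
        kwargs["seed"] = int(overrides["seed"])
    return replace(cfg, **kwargs)


__all__ = [
    "DEFAULT_RANK_ORDER", "MatchingConfig", "ScoringConfig", "RunConfig", "load_config",
]
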