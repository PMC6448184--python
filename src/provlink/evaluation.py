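"""Recall/precision assessment of predicted links against ground truth.

A predicted link is a true positive iff its (license number, NPI) pair is
in the truth table — link-level identity, not field-value agreement.
Truth rows with no NPI (providers with no national record) contribute to
neither TP nor FN; any link predicted for them is a false positive.
False negatives are attributed to their injected error channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InputError, UndefinedMetricError
from .synthetic_data import GroundTruthLink


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    recall: float | None
    precision: float | None
    error_breakdown: dict[str, int] = field(default_factory=dict)
    fn_licenses: tuple[str, ...] = ()
    fp_links: tuple[tuple[str, str], ...] = ()

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "recall": self.recall, "precision": self.precision,
            "error_breakdown": dict(self.error_breakdown),
        }

    def to_text(self) -> str:
        lines = [
            f"tp        {self.tp}",
            f"fp        {self.fp}",
            f"fn        {self.fn}",
            f"recall    {'n/a' if self.recall is None else f'{self.recall:.4f}'}",
            f"precision {'n/a' if self.precision is None else f'{self.precision:.4f}'}",
        ]
        for label in sorted(self.error_breakdown):
            lines.append(f"fn[{label}] {self.error_breakdown[label]}")
        return "\n".join(lines)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN)."""
    if tp + fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn == 0")
    return tp / (tp + fn)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP)."""
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp == 0")
    return tp / (tp + fp)


def _predicted_pairs(predicted: Iterable) -> list[tuple[str, str]]:
    pairs = []
    for item in predicted:
        if isinstance(item, tuple):
            pairs.append((str(item[0]), str(item[1])))
        else:  # LinkedProviderRecord-shaped
            pairs.append((item.license_number, item.npi))
    return pairs


def compare_to_truth(predicted: Iterable, truth: Sequence[GroundTruthLink]) -> EvaluationReport:
    """Score predicted links (records or (license, npi) pairs) against truth."""
    pairs = _predicted_pairs(predicted)
    truth_by_license = {t.license_number: t for t in truth}

    unknown = [lic for lic, _ in pairs if lic not in truth_by_license]
    if unknown:
        raise InputError(
            f"predicted licenses not covered by the truth table: {sorted(set(unknown))[:5]}"
        )

    true_pairs = {(t.license_number, t.npi) for t in truth if t.npi is not None}
    predicted_set = set(pairs)
    tp_pairs = predicted_set & true_pairs
    fp_pairs = predicted_set - true_pairs
    fn_pairs = true_pairs - predicted_set

    tp, fp, fn = len(tp_pairs), len(fp_pairs), len(fn_pairs)
    fn_licenses = tuple(sorted(lic for lic, _ in fn_pairs))
    breakdown = classify_false_results(fn_licenses, truth)
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn,
        recall=recall(tp, fn) if tp + fn else None,
        precision=precision(tp, fp) if tp + fp else None,
        error_breakdown=breakdown,
        fn_licenses=fn_licenses,
        fp_links=tuple(sorted(fp_pairs)),
    )


def classify_false_results(
    fn_licenses: Iterable[str],
    truth: Sequence[GroundTruthLink],
) -> dict[str, int]:
    """Attribute each false negative to its injected error channel."""
    truth_by_license = {t.license_number: t for t in truth}
    breakdown: dict[str, int] = {}
    for lic in fn_licenses:
        link = truth_by_license.get(lic)
        labels = sorted(link.error_labels) if link else ["other"]
        for label in labels:
            if label == "none":
                label = "other"
            breakdown[label] = breakdown.get(label, 0) + 1
    return breakdown


__all__ = [
    "EvaluationReport", "recall", "precision",
    "compare_to_truth", "classify_false_results",
]
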