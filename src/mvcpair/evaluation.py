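"""Scoring a match report against known pairings.

Counting is per *bone*, not per pair: a correctly declared pair
contributes two true positives (each bone was correctly placed with its
antimere); each bone of a wrongly declared pair is a false positive (it
asserts a match that does not exist — even if that bone does have a true
partner elsewhere); a truly paired bone left unmatched is a false
negative; a true singleton left unmatched is a true negative. Then

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)

so sensitivity measures how reliably bones are returned to their true
partner and specificity how reliably unmatched bones are recognised as
such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import MvcError
from .matching import MatchReport, Truth


@dataclass
class ConfusionCounts:
    """Per-bone confusion counts for pair-matching."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise MvcError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return None if denom == 0 else self.tp / denom

    @property
    def specificity(self) -> Optional[float]:
        denom = self.tn + self.fp
        return None if denom == 0 else self.tn / denom

    @property
    def sensitivity_percent(self) -> Optional[int]:
        """Sensitivity rounded to the whole percent, for display."""
        s = self.sensitivity
        return None if s is None else round(100.0 * s)

    @property
    def specificity_percent(self) -> Optional[int]:
        s = self.specificity
        return None if s is None else round(100.0 * s)


@dataclass
class EvaluationResult:
    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        """Confusion table formatted for a report."""
        def pct(x: Optional[float]) -> str:
            return "n/a" if x is None else f"{round(100.0 * x)} %"

        return "\n".join(
            [
                "| Quantity | Count |",
                "| --- | --- |",
                f"| True positives | {self.counts.tp} |",
                f"| False negatives | {self.counts.fn} |",
                f"| False positives | {self.counts.fp} |",
                f"| True negatives | {self.counts.tn} |",
                f"| Sensitivity | {pct(self.sensitivity)} |",
                f"| Specificity | {pct(self.specificity)} |",
            ]
        )


def evaluate_counts(counts: ConfusionCounts) -> EvaluationResult:
    """Sensitivity/specificity arithmetic on given confusion counts."""
    return EvaluationResult(counts, counts.sensitivity, counts.specificity)


def score(report: MatchReport, truth: Truth) -> EvaluationResult:
    """Score declared pairs and singletons against the known pairings.

    Every bone contributes exactly one count. A bone in a declared pair is
    TP when the pair is correct and FP otherwise; an undeclared bone is FN
    when it truly has a partner and TN when it is a true singleton.
    """
    truth_lefts = truth.left_ids
    truth_rights = truth.right_ids
    report_lefts = {l for l, _, _ in report.declared_pairs} | {
        i for i, s in report.declared_singletons if s == "left"
    }
    report_rights = {r for _, r, _ in report.declared_pairs} | {
        i for i, s in report.declared_singletons if s == "right"
    }
    missing = (report_lefts - truth_lefts) | (report_rights - truth_rights)
    if missing:
        raise MvcError(f"ids in report missing from truth: {sorted(missing)}")

    tp = fp = fn = tn = 0
    for left, right, _ in report.declared_pairs:
        if truth.pairs.get(left) == right:
            tp += 2
        else:
            fp += 2
    paired = report.paired_lefts | report.paired_rights
    for bone in truth_lefts | truth_rights:
        if bone in paired:
            continue
        if bone in truth.left_singletons or bone in truth.right_singletons:
            tn += 1
        else:
            fn += 1
    counts = ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)
    return evaluate_counts(counts)
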