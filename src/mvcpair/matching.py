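"""Pair declaration from a comparison matrix, and the cutoff analysis.

The matching rule is *mutual best*: a left and a right bone are declared a
pair only when each is the other's lowest-value candidate. The three
lowest candidates of every bone are retained in the report so an analyst
can audit near-misses (the classic confusion being: left A's best is
right B, but right B's best is left C — no pair is declared). A single
distance cutoff is deliberately not used for declaration; the threshold
analysis quantifies why, by counting how many non-pair values fall below a
mean + 2 SD cutoff fitted to the true-pair values.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import MvcError
from .mvc import ComparisonMatrix

logger = logging.getLogger(__name__)

AGREEMENT_BEST = "best"
AGREEMENT_TOPK = "topk"


@dataclass
class Truth:
    """Known pairings: the gold standard a match report is scored against."""

    pairs: dict[str, str]
    left_singletons: set[str] = field(default_factory=set)
    right_singletons: set[str] = field(default_factory=set)

    @property
    def left_ids(self) -> set[str]:
        return set(self.pairs) | self.left_singletons

    @property
    def right_ids(self) -> set[str]:
        return set(self.pairs.values()) | self.right_singletons

    def partner_of(self, bone_id: str) -> Optional[str]:
        if bone_id in self.pairs:
            return self.pairs[bone_id]
        for left, right in self.pairs.items():
            if right == bone_id:
                return left
        return None

    def to_csv(self, path: str | Path) -> Path:
        """CSV with columns ``left_id,right_id``; an empty field marks a
        singleton on the other side."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["left_id", "right_id"])
            for left, right in sorted(self.pairs.items()):
                writer.writerow([left, right])
            for left in sorted(self.left_singletons):
                writer.writerow([left, ""])
            for right in sorted(self.right_singletons):
                writer.writerow(["", right])
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Truth":
        pairs: dict[str, str] = {}
        left_single: set[str] = set()
        right_single: set[str] = set()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"left_id", "right_id"}.issubset(
                reader.fieldnames
            ):
                raise MvcError(f"truth file {path} must have columns left_id,right_id")
            for row in reader:
                left = (row["left_id"] or "").strip()
                right = (row["right_id"] or "").strip()
                if left and right:
                    if left in pairs:
                        raise MvcError(f"truth file {path}: duplicate left id {left!r}")
                    pairs[left] = right
                elif left:
                    left_single.add(left)
                elif right:
                    right_single.add(right)
        return cls(pairs, left_single, right_single)


@dataclass
class MatchReport:
    """Declared pairs, declared singletons, and top-k audit evidence."""

    declared_pairs: list[tuple[str, str, float]]
    declared_singletons: list[tuple[str, str]]
    top_candidates: dict[str, dict[str, list[tuple[str, float]]]] = field(
        default_factory=lambda: {"left": {}, "right": {}}
    )

    def __post_init__(self) -> None:
        used: set[str] = set()
        for left, right, _ in self.declared_pairs:
            for bone in (left, right):
                if bone in used:
                    raise MvcError(f"bone {bone!r} assigned to two pairs")
                used.add(bone)

    @property
    def paired_lefts(self) -> set[str]:
        return {l for l, _, _ in self.declared_pairs}

    @property
    def paired_rights(self) -> set[str]:
        return {r for _, r, _ in self.declared_pairs}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "declared_pairs": [
                {"left_id": l, "right_id": r, "value_mm": v}
                for l, r, v in self.declared_pairs
            ],
            "declared_singletons": [
                {"id": i, "side": s} for i, s in self.declared_singletons
            ],
            "top_candidates": {
                side: {
                    bone: [{"candidate": c, "value_mm": v} for c, v in cands]
                    for bone, cands in per_side.items()
                }
                for side, per_side in self.top_candidates.items()
            },
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "MatchReport":
        payload = json.loads(Path(path).read_text())
        return cls(
            [
                (p["left_id"], p["right_id"], float(p["value_mm"]))
                for p in payload["declared_pairs"]
            ],
            [(s["id"], s["side"]) for s in payload["declared_singletons"]],
            {
                side: {
                    bone: [(c["candidate"], float(c["value_mm"])) for c in cands]
                    for bone, cands in per_side.items()
                }
                for side, per_side in payload.get("top_candidates", {}).items()
            },
        )

    def to_tsv(self, path: str | Path | None = None) -> str:
        """Human-readable table: declared pairs with values, then singletons."""
        lines = ["kind\tleft_id\tright_id\tvalue_mm"]
        for left, right, value in self.declared_pairs:
            lines.append(f"pair\t{left}\t{right}\t{value:.6g}")
        for bone, side in self.declared_singletons:
            left = bone if side == "left" else ""
            right = bone if side == "right" else ""
            lines.append(f"singleton\t{left}\t{right}\t")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _ranked_candidates(
    values: np.ndarray, ids: list[str], k: int
) -> list[tuple[str, float]]:
    finite = np.isfinite(values)
    order = np.argsort(values[finite], kind="stable")
    kept = np.flatnonzero(finite)[order][:k]
    return [(ids[i], float(values[i])) for i in kept]


def mutual_match(matrix: ComparisonMatrix, k: int = 3, agreement: str = AGREEMENT_BEST) -> MatchReport:
    """Declare pairs by mutual agreement over the comparison matrix.

    Under the default ``best`` agreement a pair (L, R) is declared iff R is
    L's single lowest-value candidate and L is R's. The looser ``topk``
    agreement declares mutual-best-within-top-k instead (resolving multiple
    claimants per bone by lowest value). Ties for the lowest value are
    declared for neither candidate and logged. Failed (NaN) cells are
    absent candidates. The top-k candidate lists of every bone are retained
    for audit.
    """
    values = matrix.values.to_numpy(dtype=float)
    if values.size == 0:
        raise MvcError("comparison matrix is empty")
    left_ids = matrix.left_ids
    right_ids = matrix.right_ids

    top_left = {
        lid: _ranked_candidates(values[i, :], right_ids, k)
        for i, lid in enumerate(left_ids)
    }
    top_right = {
        rid: _ranked_candidates(values[:, j], left_ids, k)
        for j, rid in enumerate(right_ids)
    }

    def best_of(cands: list[tuple[str, float]], row: np.ndarray) -> Optional[str]:
        if not cands:
            return None
        best_id, best_val = cands[0]
        # an exact tie for the minimum is declared for neither candidate
        if np.sum(row[np.isfinite(row)] == best_val) > 1:
            logger.warning("tie for lowest value at %.6g mm; no pair declared", best_val)
            return None
        return best_id

    best_left = {
        lid: best_of(top_left[lid], values[i, :]) for i, lid in enumerate(left_ids)
    }
    best_right = {
        rid: best_of(top_right[rid], values[:, j]) for j, rid in enumerate(right_ids)
    }

    pairs: list[tuple[str, str, float]] = []
    if agreement == AGREEMENT_BEST:
        for i, lid in enumerate(left_ids):
            rid = best_left[lid]
            if rid is not None and best_right.get(rid) == lid:
                pairs.append((lid, rid, float(matrix.values.loc[lid, rid])))
    elif agreement == AGREEMENT_TOPK:
        claims: dict[str, list[tuple[float, str]]] = {}
        for lid in left_ids:
            for rid, val in top_left[lid]:
                if any(c == lid for c, _ in top_right.get(rid, [])):
                    claims.setdefault(rid, []).append((val, lid))
        used_lefts: set[str] = set()
        for rid in right_ids:
            for val, lid in sorted(claims.get(rid, [])):
                if lid not in used_lefts:
                    pairs.append((lid, rid, val))
                    used_lefts.add(lid)
                    break
    else:
        raise ValueError(f"agreement must be 'best' or 'topk', got {agreement!r}")

    paired = {l for l, _, _ in pairs} | {r for _, r, _ in pairs}
    singletons = [(lid, "left") for lid in left_ids if lid not in paired]
    singletons += [(rid, "right") for rid in right_ids if rid not in paired]
    return MatchReport(pairs, singletons, {"left": top_left, "right": top_right})


@dataclass
class ThresholdAnalysis:
    """Mean + 2 SD cutoff fitted to true-pair values, and what it captures."""

    mean: float
    sd: float
    cutoff: float
    n_true_values_captured: int
    n_true_values: int
    n_false_values_below_cutoff: int

    def __post_init__(self) -> None:
        if not math.isclose(self.cutoff, self.mean + 2.0 * self.sd, rel_tol=1e-12):
            raise MvcError("cutoff must equal mean + 2*sd")


def threshold_analysis(matrix: ComparisonMatrix, truth: Truth) -> ThresholdAnalysis:
    """Fit a mean + 2 SD cutoff to the true-pair values of a matrix.

    The sample standard deviation uses the n-1 denominator. Reports how
    many true-pair values the cutoff captures and how many non-pair cells
    also fall at or below it — the latter is what makes a single cutoff
    unusable as a declaration rule whenever the two distributions overlap.
    """
    true_values = []
    for left, right in truth.pairs.items():
        if left in matrix.values.index and right in matrix.values.columns:
            v = float(matrix.values.loc[left, right])
            if np.isfinite(v):
                true_values.append(v)
    if len(true_values) < 2:
        raise MvcError(
            f"threshold analysis needs >=2 true-pair values, got {len(true_values)}"
        )
    true_values = np.asarray(true_values)
    mean = float(true_values.mean())
    sd = float(true_values.std(ddof=1))
    cutoff = mean + 2.0 * sd

    all_values = matrix.values.to_numpy(dtype=float)
    mask_true = np.zeros_like(all_values, dtype=bool)
    for left, right in truth.pairs.items():
        if left in matrix.values.index and right in matrix.values.columns:
            mask_true[
                matrix.values.index.get_loc(left), matrix.values.columns.get_loc(right)
            ] = True
    non_pair = all_values[~mask_true]
    non_pair = non_pair[np.isfinite(non_pair)]
    return ThresholdAnalysis(
        mean=mean,
        sd=sd,
        cutoff=cutoff,
        n_true_values_captured=int((true_values <= cutoff).sum()),
        n_true_values=len(true_values),
        n_false_values_below_cutoff=int((non_pair <= cutoff).sum()),
    )
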