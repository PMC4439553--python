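"""Precision / recall / F1 from confusion counts.

Precision is the proportion of true positives among positive
predictions; recall the proportion of true positives among actual
positives.  Ratios are computed with exact rational arithmetic and only
converted to floats on access, so pooled (micro-averaged) numbers are
identical to the metrics of the summed confusion counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path


@dataclass(frozen=True)
class Metrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def precision(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return float(Fraction(self.tp, self.tp + self.fp))

    @property
    def recall(self) -> float | None:
        if self.tp + self.fn == 0:
            return None
        return float(Fraction(self.tp, self.tp + self.fn))

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        if p + r == 0:
            return 0.0
        # harmonic mean via exact counts: 2tp / (2tp + fp + fn)
        return float(Fraction(2 * self.tp, 2 * self.tp + self.fp + self.fn))

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def compute_metrics(tp: int, fp: int, fn: int) -> Metrics:
    return Metrics(tp=tp, fp=fp, fn=fn)


def pool(per_fold: list[Metrics]) -> Metrics:
    """Micro-average: sum confusion counts across folds, then divide."""
    total = Metrics()
    for m in per_fold:
        total = total + m
    return total


def macro_average(per_fold: list[Metrics]) -> dict:
    """Unweighted mean of per-fold rates, skipping undefined folds."""

    def mean(values: list[float | None]) -> float | None:
        defined = [v for v in values if v is not None]
        return sum(defined) / len(defined) if defined else None

    return {
        "precision": mean([m.precision for m in per_fold]),
        "recall": mean([m.recall for m in per_fold]),
        "f1": mean([m.f1 for m in per_fold]),
    }


def write_report(metrics: dict, path: str | Path) -> None:
    """Emit a metrics dict (JSON for .json paths, TSV otherwise)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(metrics, indent=2, default=str) + "\n")
    else:
        lines = ["metric\tvalue"]
        lines += [f"{k}\t{v}" for k, v in metrics.items()]
        path.write_text("\n".join(lines) + "\n")
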