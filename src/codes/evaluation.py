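"""Binary-classification metrics and CAPRI-style top-N success reporting.

Positive class = correct decoy.  Zero-denominator conventions: precision or
recall with an empty denominator are reported as 0 (flagged degenerate), F1
with P = R = 0 is 0, and MCC with any zero factor in its denominator is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from codes.capri import quality_rank
from codes.exceptions import CodesError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the class roles exchanged (for per-class metrics)."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricsSet:
    precision: float
    recall: float
    accuracy: float
    f1: float
    mcc: float
    degenerate: bool = False


@dataclass(frozen=True)
class ClassifiedMetrics:
    """Metrics for both class roles, as reported per correct/incorrect class."""

    correct: MetricsSet
    incorrect: MetricsSet
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        def ms(m: MetricsSet) -> dict:
            return {
                "precision": m.precision,
                "recall": m.recall,
                "accuracy": m.accuracy,
                "f1": m.f1,
                "mcc": m.mcc,
            }

        return {
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            "correct": ms(self.correct),
            "incorrect": ms(self.incorrect),
        }


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape or labels.size < 1:
        raise CodesError("labels and predictions must be equal-length, non-empty")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricsSet:
    """Precision, recall, accuracy, F1 and MCC from confusion counts."""
    degenerate = False
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, degenerate = 0.0, True
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, degenerate = 0.0, True
    accuracy = (c.tp + c.tn) / c.total if c.total else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricsSet(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        mcc=mcc,
        degenerate=degenerate,
    )


def classified_metrics(labels: Sequence[int], predictions: Sequence[int]) -> ClassifiedMetrics:
    c = confusion(labels, predictions)
    return ClassifiedMetrics(
        correct=metrics(c), incorrect=metrics(c.swapped()), counts=c
    )


@dataclass(frozen=True)
class TargetSuccess:
    target_id: str
    n_acceptable_or_better: int
    n_medium_or_better: int
    n_high: int
    reachable: bool  # target has >= 1 correct decoy among those evaluated

    def format_hits(self) -> str:
        """'9/3***/5**'-style cell: hits, then high (***) and medium (**)."""
        if self.n_acceptable_or_better == 0:
            return "0"
        parts = [str(self.n_acceptable_or_better)]
        if self.n_high:
            parts.append(f"{self.n_high}***")
        n_medium = self.n_medium_or_better - self.n_high
        if n_medium:
            parts.append(f"{n_medium}**")
        return "/".join(parts)


@dataclass(frozen=True)
class SuccessReport:
    top_n: int
    per_target: Tuple[TargetSuccess, ...]

    @property
    def n_targets_with_hit(self) -> int:
        return sum(1 for t in self.per_target if t.n_acceptable_or_better > 0)

    @property
    def n_targets_with_medium(self) -> int:
        return sum(1 for t in self.per_target if t.n_medium_or_better > 0)

    @property
    def n_targets_with_high(self) -> int:
        return sum(1 for t in self.per_target if t.n_high > 0)

    def to_dict(self) -> dict:
        return {
            "top_n": self.top_n,
            "totals": {
                "acceptable_or_better": self.n_targets_with_hit,
                "medium_or_better": self.n_targets_with_medium,
                "high": self.n_targets_with_high,
            },
            "per_target": [
                {
                    "target_id": t.target_id,
                    "acceptable_or_better": t.n_acceptable_or_better,
                    "medium_or_better": t.n_medium_or_better,
                    "high": t.n_high,
                    "reachable": t.reachable,
                    "cell": t.format_hits(),
                }
                for t in self.per_target
            ],
        }


def success_rate(
    rankings: Mapping[str, Sequence[str]],
    qualities: Mapping[str, Mapping[str, str]],
    n: int = 10,
) -> SuccessReport:
    """Per-target counts of acceptable/medium/high decoys within the top N.

    ``rankings`` maps target -> ordered model ids (best first); ``qualities``
    maps target -> model id -> quality label.  Targets without any correct
    decoy available are reported but flagged unreachable.
    """
    if n < 1:
        raise CodesError("top-N requires N >= 1")
    per_target = []
    for target in sorted(rankings):
        quals = qualities[target]
        top = list(rankings[target])[:n]
        ranks = [quality_rank(quals[m]) for m in top if m in quals]
        acc = sum(1 for r in ranks if r >= 1)
        med = sum(1 for r in ranks if r >= 2)
        high = sum(1 for r in ranks if r >= 3)
        reachable = any(quality_rank(q) >= 1 for q in quals.values())
        per_target.append(
            TargetSuccess(
                target_id=target,
                n_acceptable_or_better=acc,
                n_medium_or_better=med,
                n_high=high,
                reachable=reachable,
            )
        )
    return SuccessReport(top_n=n, per_target=tuple(per_target))


def aggregate_over_repeats(
    repeats: Sequence[MetricsSet],
) -> Dict[str, Tuple[float, Optional[float]]]:
    """Element-wise mean and sample sd of metric sets over repeats.

    With a single repeat the sd is reported as None.
    """
    if not repeats:
        raise CodesError("no repeats to aggregate")
    fields = ("precision", "recall", "accuracy", "f1", "mcc")
    out: Dict[str, Tuple[float, Optional[float]]] = {}
    for name in fields:
        values = np.asarray([getattr(m, name) for m in repeats], dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else None
        out[name] = (mean, sd)
    return out
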