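"""Dataset construction: balanced and capped-unbalanced manifests, target-level
splits.

All sampling is driven by per-target substreams derived from a single run
seed by hashing the target id, so adding or removing a target never perturbs
another target's sample.  Binary labels: incorrect = 0, correct = 1.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from codes.capri import CORRECT_QUALITIES
from codes.exceptions import CodesError, ManifestError

logger = logging.getLogger(__name__)

LABEL_INCORRECT = 0
LABEL_CORRECT = 1


@dataclass(frozen=True)
class DecoyRecord:
    model_id: str
    quality: str
    clash_kept: bool = True

    @property
    def label(self) -> int:
        return LABEL_CORRECT if self.quality in CORRECT_QUALITIES else LABEL_INCORRECT


@dataclass
class LabeledDecoySet:
    """Per-target labeled decoys; only clash-kept decoys enter any dataset."""

    targets: Dict[str, List[DecoyRecord]]

    def kept(self, target: str) -> List[DecoyRecord]:
        return [r for r in self.targets[target] if r.clash_kept]

    def correct(self, target: str) -> List[DecoyRecord]:
        return [r for r in self.kept(target) if r.label == LABEL_CORRECT]

    def incorrect(self, target: str) -> List[DecoyRecord]:
        return [r for r in self.kept(target) if r.label == LABEL_INCORRECT]


@dataclass(frozen=True)
class DatasetSplit:
    scheme: str
    train_targets: Tuple[str, ...]
    validation_targets: Tuple[str, ...]
    repeat_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.train_targets) & set(self.validation_targets):
            raise ManifestError("train and validation targets overlap")


def _target_rng(seed: int, target_id: str) -> np.random.Generator:
    """Independent per-target substream: stable across target-set changes."""
    digest = hashlib.sha256(target_id.encode()).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng([seed, sub])


def drop_targets_without_correct(sets: LabeledDecoySet) -> LabeledDecoySet:
    """Remove targets with zero correct decoys (among clash-kept ones)."""
    kept = {}
    removed = []
    for target in sets.targets:
        if sets.correct(target):
            kept[target] = sets.targets[target]
        else:
            removed.append(target)
    if removed:
        logger.info("removed %d target(s) without correct decoys: %s", len(removed), removed)
    return LabeledDecoySet(kept)


def _manifest_frame(rows: List[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["target_id", "model_id", "label", "quality"])


def build_balanced(sets: LabeledDecoySet, seed: int) -> pd.DataFrame:
    """Per target: all correct decoys plus an equal-size random sample of
    incorrect ones (without replacement)."""
    rows: List[tuple] = []
    for target in sorted(sets.targets):
        correct = sets.correct(target)
        incorrect = sets.incorrect(target)
        if not correct:
            logger.warning("%s: no correct decoys, skipped from balanced set", target)
            continue
        n = len(correct)
        rng = _target_rng(seed, target)
        if len(incorrect) < n:
            logger.warning(
                "%s: only %d incorrect for %d correct; taking all",
                target, len(incorrect), n,
            )
            sampled = list(incorrect)
        else:
            idx = rng.choice(len(incorrect), size=n, replace=False)
            sampled = [incorrect[i] for i in sorted(idx)]
        for r in correct:
            rows.append((target, r.model_id, LABEL_CORRECT, r.quality))
        for r in sampled:
            rows.append((target, r.model_id, LABEL_INCORRECT, r.quality))
    return _manifest_frame(rows)


def build_3k(
    sets: LabeledDecoySet,
    seed: int,
    total: int = 3000,
    cap_correct: int = 600,
) -> pd.DataFrame:
    """Per target: up to ``cap_correct`` correct decoys plus random incorrect
    decoys until ``total`` decoys are collected."""
    rows: List[tuple] = []
    for target in sorted(sets.targets):
        correct = sets.correct(target)
        incorrect = sets.incorrect(target)
        rng = _target_rng(seed, target)
        if len(correct) > cap_correct:
            idx = rng.choice(len(correct), size=cap_correct, replace=False)
            chosen_correct = [correct[i] for i in sorted(idx)]
        else:
            chosen_correct = list(correct)
        n_incorrect = total - len(chosen_correct)
        if len(incorrect) < n_incorrect:
            logger.warning(
                "%s: supply short (%d incorrect available, %d wanted); taking all",
                target, len(incorrect), n_incorrect,
            )
            chosen_incorrect = list(incorrect)
        else:
            idx = rng.choice(len(incorrect), size=n_incorrect, replace=False)
            chosen_incorrect = [incorrect[i] for i in sorted(idx)]
        for r in chosen_correct:
            rows.append((target, r.model_id, LABEL_CORRECT, r.quality))
        for r in chosen_incorrect:
            rows.append((target, r.model_id, LABEL_INCORRECT, r.quality))
    return _manifest_frame(rows)


def split_bm4_bm5up(target_tags: Mapping[str, str]) -> DatasetSplit:
    """Deterministic split: BM4-tagged targets train, BM5-update validate."""
    train, validation = [], []
    for target in sorted(target_tags):
        tag = target_tags[target]
        if tag == "BM4":
            train.append(target)
        elif tag in ("BM5-update", "BM5up", "BM5_update"):
            validation.append(target)
        else:
            raise ManifestError(f"{target}: unknown benchmark tag {tag!r}")
    if not validation:
        logger.warning("bm4_vs_bm5up split has an empty validation set")
    return DatasetSplit(
        scheme="bm4_vs_bm5up",
        train_targets=tuple(train),
        validation_targets=tuple(validation),
    )


def repeated_random_splits(
    targets: Sequence[str],
    n_validation: int = 64,
    repeats: int = 10,
    seed: int = 0,
) -> List[DatasetSplit]:
    """Seeded repeated random target-level splits (validation size fixed)."""
    targets = sorted(set(targets))
    if n_validation >= len(targets):
        raise CodesError(
            f"n_validation={n_validation} must be < number of targets ({len(targets)})"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for rep in range(repeats):
        idx = rng.choice(len(targets), size=n_validation, replace=False)
        validation = tuple(targets[i] for i in sorted(idx))
        train = tuple(t for t in targets if t not in set(validation))
        splits.append(
            DatasetSplit(
                scheme="repeated_random",
                train_targets=train,
                validation_targets=validation,
                repeat_index=rep,
                seed=seed,
            )
        )
    return splits


def manifest_to_tsv(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def manifest_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})


def labeled_set_from_metrics(
    metrics_by_target: Mapping[str, Sequence],
    screens: Optional[Mapping[str, object]] = None,
) -> LabeledDecoySet:
    """Build a LabeledDecoySet from per-target CapriMetrics and clash screens."""
    targets: Dict[str, List[DecoyRecord]] = {}
    for target, records in metrics_by_target.items():
        discarded = set()
        if screens is not None and target in screens:
            discarded = set(screens[target].discarded_ids)
        targets[target] = [
            DecoyRecord(
                model_id=m.model_id,
                quality=m.quality,
                clash_kept=m.model_id not in discarded,
            )
            for m in records
        ]
    return LabeledDecoySet(targets)
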