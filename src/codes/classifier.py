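"""Class-weighted random-forest training, importance-driven forward feature
selection, coordinate-wise hyperparameter tuning, prediction and ranking.

Class weights enter as per-class sample weights at fit time.  The default
hyperparameters are the tuned values: 100 trees, min_samples_split 10, and
class weights 1.2 (incorrect) / 0.1 (correct).  Feature importance is the
forest's mean impurity decrease; permutation importance is available as a
diagnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from codes.evaluation import classified_metrics
from codes.exceptions import CodesError, DegenerateLabelError, SchemaError
from codes.features import FeatureTable, NormalizationStats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparameters:
    n_trees: int = 100
    min_samples_split: int = 10
    class_weight_incorrect: float = 1.2
    class_weight_correct: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.min_samples_split) <= 0:
            raise CodesError("tree count and min_samples_split must be positive")
        if min(self.class_weight_incorrect, self.class_weight_correct) <= 0:
            raise CodesError("class weights must be positive")


@dataclass
class TrainedClassifier:
    forest: RandomForestClassifier
    selected_features: List[str]
    importances: Dict[str, float]
    normalization: Optional[NormalizationStats]
    hyperparameters: Hyperparameters
    training_manifest: str = ""

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "selected_features": self.selected_features,
            "importances": self.importances,
            "normalization": None
            if self.normalization is None
            else self.normalization.to_dict(),
            "hyperparameters": {
                "n_trees": self.hyperparameters.n_trees,
                "min_samples_split": self.hyperparameters.min_samples_split,
                "class_weight_incorrect": self.hyperparameters.class_weight_incorrect,
                "class_weight_correct": self.hyperparameters.class_weight_correct,
                "seed": self.hyperparameters.seed,
            },
            "training_manifest": self.training_manifest,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.forest, directory / "forest.joblib")

    @classmethod
    def load(cls, directory) -> "TrainedClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        norm = meta["normalization"]
        return cls(
            forest=joblib.load(directory / "forest.joblib"),
            selected_features=list(meta["selected_features"]),
            importances=dict(meta["importances"]),
            normalization=None if norm is None else NormalizationStats.from_dict(norm),
            hyperparameters=Hyperparameters(**meta["hyperparameters"]),
            training_manifest=meta.get("training_manifest", ""),
        )


def _sample_weights(labels: np.ndarray, hp: Hyperparameters) -> np.ndarray:
    return np.where(labels == 0, hp.class_weight_incorrect, hp.class_weight_correct)


def _fit_forest(
    x: pd.DataFrame, y: np.ndarray, hp: Hyperparameters
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=hp.n_trees,
        min_samples_split=hp.min_samples_split,
        random_state=hp.seed,
        n_jobs=1,
    )
    forest.fit(x.values, y, sample_weight=_sample_weights(y, hp))
    return forest


def train(
    features: FeatureTable,
    labels: Sequence[int],
    hp: Hyperparameters = Hyperparameters(),
    normalization: Optional[NormalizationStats] = None,
    training_manifest: str = "",
) -> TrainedClassifier:
    """Fit a class-weighted forest on (already normalized) training rows."""
    y = np.asarray(labels, dtype=int)
    if len(y) != len(features):
        raise CodesError("labels length does not match feature rows")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("training labels contain a single class")
    if features.data.isna().any().any():
        raise CodesError("training features contain missing values; impute first")
    forest = _fit_forest(features.data, y, hp)
    importances = dict(zip(features.registry, map(float, forest.feature_importances_)))
    return TrainedClassifier(
        forest=forest,
        selected_features=features.registry,
        importances=importances,
        normalization=normalization,
        hyperparameters=hp,
        training_manifest=training_manifest,
    )


def predict(model: TrainedClassifier, rows: FeatureTable) -> pd.DataFrame:
    """Per-row (label, score); score = fraction of trees voting correct.

    Normalization is applied with the model's stored statistics when present.
    """
    missing = [f for f in model.selected_features if f not in rows.data.columns]
    if missing:
        raise SchemaError(f"rows lack selected feature(s): {missing}")
    x = rows.data[model.selected_features]
    if model.normalization is not None:
        mu = model.normalization.mu[model.selected_features]
        sigma = model.normalization.sigma[model.selected_features]
        x = (x - mu) / sigma
    votes = np.zeros(len(x))
    for tree in model.forest.estimators_:
        votes += (tree.predict(x.values) == 1)
    score = votes / len(model.forest.estimators_)
    label = (score >= 0.5).astype(int)
    return pd.DataFrame({"label": label, "score": score}, index=x.index)


def rank_decoys(model: TrainedClassifier, rows: FeatureTable) -> List[str]:
    """Model ids of one target's decoys, best first.

    Descending by vote score; ties broken by the consensus contact score when
    present, then lexicographically by model id.
    """
    preds = predict(model, rows)
    model_ids = preds.index.get_level_values("model_id")
    consensus = (
        rows.data["CONSRANK_score"].values
        if "CONSRANK_score" in rows.data.columns
        else np.zeros(len(preds))
    )
    order = sorted(
        range(len(preds)),
        key=lambda i: (-preds["score"].iloc[i], -consensus[i], model_ids[i]),
    )
    return [model_ids[i] for i in order]


def _validation_mcc(
    train_x: FeatureTable,
    train_y: Sequence[int],
    val_x: FeatureTable,
    val_y: Sequence[int],
    hp: Hyperparameters,
    feature_subset: Optional[Sequence[str]] = None,
) -> Tuple[float, float]:
    """(MCC, accuracy) on the validation rows for a forest fit on train rows."""
    if feature_subset is not None:
        train_x = FeatureTable(train_x.data[list(feature_subset)].copy())
        val_x = FeatureTable(val_x.data[list(feature_subset)].copy())
    model = train(train_x, train_y, hp)
    preds = predict(model, val_x)
    cm = classified_metrics(np.asarray(val_y, dtype=int), preds["label"].values)
    return cm.correct.mcc, cm.correct.accuracy


def forward_select(
    train_features: FeatureTable,
    train_labels: Sequence[int],
    val_features: FeatureTable,
    val_labels: Sequence[int],
    importance_threshold: float = 0.01,
    hp: Hyperparameters = Hyperparameters(),
) -> Tuple[List[str], pd.DataFrame]:
    """Bottom-up forward selection driven by full-model impurity importance.

    Features are ranked by the importance of a forest fit on all features,
    then added one at a time from highest to lowest, recording validation
    accuracy and MCC at each step.  Returns the features whose full-model
    importance is at or above the threshold, plus the metric trace.
    """
    full = train(train_features, train_labels, hp)
    ranked = sorted(full.importances, key=lambda f: (-full.importances[f], f))
    trace_rows = []
    for step in range(1, len(ranked) + 1):
        subset = ranked[:step]
        mcc, acc = _validation_mcc(
            train_features, train_labels, val_features, val_labels, hp, subset
        )
        trace_rows.append(
            {
                "step": step,
                "feature_added": ranked[step - 1],
                "importance": full.importances[ranked[step - 1]],
                "mcc": mcc,
                "accuracy": acc,
            }
        )
    trace = pd.DataFrame(trace_rows)
    selected = [f for f in ranked if full.importances[f] >= importance_threshold]
    if not selected:
        logger.warning(
            "importance threshold %.3g excludes every feature; keeping top-1",
            importance_threshold,
        )
        selected = ranked[:1]
    return selected, trace


def select_common_features(
    selections: Sequence[Sequence[str]],
    importances: Optional[Sequence[Mapping[str, float]]] = None,
) -> List[str]:
    """Features common to all selections, ordered by mean importance.

    An empty intersection falls back (with a warning) to the union.
    """
    if len(selections) < 2:
        raise CodesError("need at least two selections to intersect")
    common = set(selections[0])
    for sel in selections[1:]:
        common &= set(sel)
    if not common:
        logger.warning("selections are disjoint; falling back to their union")
        common = set().union(*selections)

    def mean_importance(f: str) -> float:
        if not importances:
            return 0.0
        values = [imp.get(f, 0.0) for imp in importances]
        return sum(values) / len(values)

    return sorted(common, key=lambda f: (-mean_importance(f), f))


def tune(
    train_features: FeatureTable,
    train_labels: Sequence[int],
    val_features: FeatureTable,
    val_labels: Sequence[int],
    grid: Mapping[str, Sequence],
    defaults: Hyperparameters = Hyperparameters(),
) -> Hyperparameters:
    """Coordinate-wise hyperparameter optimization on validation MCC.

    Each parameter's grid is scanned holding the others at their defaults;
    ties keep the default value when it attains the maximum, otherwise the
    smaller value.  Recognized grid keys: n_trees, min_samples_split,
    class_weights (pairs (incorrect, correct)).
    """
    best = defaults

    def evaluate(hp: Hyperparameters) -> float:
        mcc, _ = _validation_mcc(
            train_features, train_labels, val_features, val_labels, hp
        )
        return mcc

    for param in ("n_trees", "min_samples_split", "class_weights"):
        if param not in grid or not grid[param]:
            continue
        candidates = list(grid[param])
        scores = []
        for value in candidates:
            if param == "class_weights":
                w_inc, w_cor = value
                hp = replace(defaults, class_weight_incorrect=w_inc, class_weight_correct=w_cor)
            else:
                hp = replace(defaults, **{param: value})
            scores.append(evaluate(hp))
        best_score = max(scores)
        argmax = [v for v, s in zip(candidates, scores) if s == best_score]
        if param == "class_weights":
            default_value = (defaults.class_weight_incorrect, defaults.class_weight_correct)
            chosen = default_value if tuple(default_value) in {tuple(v) for v in argmax} else min(argmax)
            best = replace(
                best, class_weight_incorrect=chosen[0], class_weight_correct=chosen[1]
            )
        else:
            default_value = getattr(defaults, param)
            chosen = default_value if default_value in argmax else min(argmax)
            best = replace(best, **{param: chosen})
    return best


def permutation_importances(
    model: TrainedClassifier,
    rows: FeatureTable,
    labels: Sequence[int],
    n_repeats: int = 5,
    seed: int = 0,
) -> Dict[str, float]:
    """Permutation importance diagnostic on held-out rows."""
    x = rows.data[model.selected_features]
    if model.normalization is not None:
        x = (x - model.normalization.mu[model.selected_features]) / model.normalization.sigma[
            model.selected_features
        ]
    result = permutation_importance(
        model.forest,
        x.values,
        np.asarray(labels, dtype=int),
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    return dict(zip(model.selected_features, map(float, result.importances_mean)))
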