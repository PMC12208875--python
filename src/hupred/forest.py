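"""Random-forest resistance classifier: split, cross-validated rank aggregation, AUC.

The classifier predicts the resistance outcome from pre-index features with an
80:20 stratified train/validation split and 5-fold cross-validation inside the
training set.  Feature importance is computed per fold (permutation importance
on the held-out fold by default; impurity importance optionally), converted to
ranks (1 = most important), and averaged across folds into a rank score; with
5 folds every rank score is a multiple of 0.2.  The composite ROC-AUC is the
AUC of the pooled out-of-fold predictions, which equals the Mann-Whitney
probability that a random resistant patient outscores a random non-resistant
one (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline

__all__ = [
    "ModelConfig",
    "RankedFeature",
    "EvaluationResult",
    "split_train_validate",
    "cross_validated_importance",
    "cross_validated_predictions",
    "composite_auc",
    "evaluate_model",
    "ranking_table",
]


@dataclass(frozen=True)
class ModelConfig:
    """Random-forest and evaluation hyperparameters.

    Tree-level defaults (500 trees, sqrt(p) features per split, minimum leaf
    size 5) and the permutation importance method are package choices; the
    split ratio and fold count are the study design.
    """

    train_fraction: float = 0.8
    n_folds: int = 5
    n_trees: int = 500
    min_leaf: int = 5
    feature_subset_rule: str = "sqrt"
    importance_method: str = "permutation"  # or "impurity"
    n_permutation_repeats: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValueError("n_trees and min_leaf must be >= 1")
        if self.importance_method not in ("permutation", "impurity"):
            raise ValueError("importance_method must be 'permutation' or 'impurity'")


@dataclass(frozen=True)
class RankedFeature:
    """Per-fold importance ranks and their mean for one variable."""

    name: str
    fold_ranks: tuple[int, ...]
    rank_score: float
    direction: int  # sign of resistant-minus-nonresistant mean


@dataclass(frozen=True)
class EvaluationResult:
    """Cross-validated model evaluation."""

    composite_auc: float
    per_fold_auc: tuple[float, ...]
    out_of_fold_predictions: pd.Series
    validation_auc: float | None = None


def _new_forest(config: ModelConfig, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            (
                "forest",
                RandomForestClassifier(
                    n_estimators=config.n_trees,
                    min_samples_leaf=config.min_leaf,
                    max_features=config.feature_subset_rule,
                    random_state=seed,
                    n_jobs=1,
                ),
            ),
        ]
    )


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")


def split_train_validate(
    features: pd.DataFrame, labels: np.ndarray, config: ModelConfig = ModelConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Seeded stratified train/validation split (default 80:20)."""
    config.validate()
    labels = np.asarray(labels, dtype=bool)
    if len(features) < 10:
        raise ValueError("need at least 10 labeled patients to split")
    _check_two_classes(labels)
    x_tr, x_va, y_tr, y_va = train_test_split(
        features,
        labels,
        train_size=config.train_fraction,
        stratify=labels,
        random_state=config.seed,
    )
    return x_tr, x_va, y_tr, y_va


def _stratified_folds(y: np.ndarray, config: ModelConfig):
    """Fold assignments, re-seeded up to 5 times if a fold lacks a class."""
    for attempt in range(5):
        kf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed + attempt
        )
        folds = list(kf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 for _, te in folds):
            return folds
    raise ValueError("could not build folds with both classes after 5 attempts")


def cross_validated_importance(
    features: pd.DataFrame, labels: np.ndarray, config: ModelConfig = ModelConfig()
) -> list[RankedFeature]:
    """Per-fold importance ranks aggregated into a mean rank score.

    Within each fold the ranks are a permutation of 1..n_features; the output
    is sorted by rank score ascending, so the ten most influential variables
    are the first ten entries.
    """
    config.validate()
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    names = list(features.columns)
    x = features.to_numpy(dtype=float)
    fold_ranks = np.empty((config.n_folds, len(names)), dtype=int)
    for k, (tr, te) in enumerate(_stratified_folds(labels, config)):
        model = _new_forest(config, config.seed + 1000 * k)
        model.fit(x[tr], labels[tr])
        if config.importance_method == "permutation":
            imp = permutation_importance(
                model,
                x[te],
                labels[te],
                n_repeats=config.n_permutation_repeats,
                random_state=config.seed + k,
                scoring="roc_auc",
            ).importances_mean
        else:
            imp = model.named_steps["forest"].feature_importances_
        fold_ranks[k] = rankdata(-imp, method="ordinal")
    mean_res = np.nanmean(x[labels], axis=0)
    mean_non = np.nanmean(x[~labels], axis=0)
    direction = np.sign(mean_res - mean_non).astype(int)
    out = [
        RankedFeature(
            name=names[j],
            fold_ranks=tuple(int(r) for r in fold_ranks[:, j]),
            rank_score=float(fold_ranks[:, j].mean()),
            direction=int(direction[j]),
        )
        for j in range(len(names))
    ]
    return sorted(out, key=lambda rf: (rf.rank_score, rf.name))


def ranking_table(ranked: list[RankedFeature], top: int | None = None) -> pd.DataFrame:
    """Rank / variable / rank-score table (most influential first)."""
    rows = ranked if top is None else ranked[:top]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "variable": [r.name for r in rows],
            "rank_score": [r.rank_score for r in rows],
            "direction": [r.direction for r in rows],
        }
    )


def cross_validated_predictions(
    features: pd.DataFrame, labels: np.ndarray, config: ModelConfig = ModelConfig()
) -> tuple[pd.Series, tuple[float, ...]]:
    """Out-of-fold probability scores and per-fold AUCs."""
    config.validate()
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    x = features.to_numpy(dtype=float)
    scores = np.empty(len(labels))
    per_fold = []
    for k, (tr, te) in enumerate(_stratified_folds(labels, config)):
        model = _new_forest(config, config.seed + 1000 * k)
        model.fit(x[tr], labels[tr])
        scores[te] = model.predict_proba(x[te])[:, 1]
        per_fold.append(float(roc_auc_score(labels[te], scores[te])))
    return pd.Series(scores, index=features.index, name="score"), tuple(per_fold)


def composite_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC of pooled out-of-fold scores.

    Equals the Mann-Whitney probability that a random resistant patient
    outscores a random non-resistant one, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    return float(roc_auc_score(labels, scores))


def evaluate_model(
    features: pd.DataFrame, labels: np.ndarray, config: ModelConfig = ModelConfig()
) -> EvaluationResult:
    """80:20 split, 5-fold CV on the training side, composite + validation AUC."""
    x_tr, x_va, y_tr, y_va = split_train_validate(features, labels, config)
    oof, per_fold = cross_validated_predictions(x_tr, y_tr, config)
    comp = composite_auc(oof.to_numpy(), y_tr)
    model = _new_forest(config, config.seed)
    model.fit(x_tr.to_numpy(dtype=float), y_tr)
    val_scores = model.predict_proba(x_va.to_numpy(dtype=float))[:, 1]
    val_auc = float(roc_auc_score(y_va, val_scores)) if len(np.unique(y_va)) == 2 else None
    return EvaluationResult(
        composite_auc=comp,
        per_fold_auc=per_fold,
        out_of_fold_predictions=oof,
        validation_auc=val_auc,
    )
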