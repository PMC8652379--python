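"""Difference-vector random-forest classification of PK-cancer pairs.

A candidate pair (PK, cancer) is represented by the difference vector
f(PK) - f(cancer) of its concept embeddings; the 100 components are the
features of a random forest whose hyperparameters are chosen by randomized
search with cross-validated AUROC.  Evaluation produces ROC and
precision-recall curves; operating thresholds are chosen either by the
geometric mean of sensitivity and specificity, sqrt(TPR * (1 - FPR)), or by
the optimal F1 score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import RandomizedSearchCV

from .embedding import EmbeddingModel

__all__ = [
    "FeatureRow",
    "SearchSpace",
    "EvaluationReport",
    "ClassifierError",
    "build_difference_features",
    "train_classifier",
    "score_pairs",
    "evaluate",
    "select_threshold",
    "rank_predictions",
    "permutation_control_auroc",
]

logger = logging.getLogger(__name__)


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRow:
    pk: str
    cancer: str
    v: np.ndarray  # f(pk) - f(cancer)
    label: int | None = None


@dataclass(frozen=True)
class SearchSpace:
    """Randomized-search ranges for the random forest."""

    n_estimators: tuple[int, ...] = tuple(range(100, 1001, 100))
    max_depth: tuple[int | None, ...] = (None,) + tuple(range(10, 101, 10))
    max_features: tuple = ("sqrt", "log2", 0.1, 0.25, 0.5, 0.75, 1.0)
    min_samples_split: tuple[int, ...] = (2, 5, 10)
    min_samples_leaf: tuple[int, ...] = (1, 2, 4)
    bootstrap: tuple[bool, ...] = (True, False)
    iterations: int = 100
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ClassifierError("iterations must be >= 1")
        for name in ("n_estimators", "max_depth", "max_features",
                     "min_samples_split", "min_samples_leaf", "bootstrap"):
            if not getattr(self, name):
                raise ClassifierError(f"empty search range {name}")

    @property
    def param_distributions(self) -> dict:
        return {
            "n_estimators": list(self.n_estimators),
            "max_depth": list(self.max_depth),
            "max_features": list(self.max_features),
            "min_samples_split": list(self.min_samples_split),
            "min_samples_leaf": list(self.min_samples_leaf),
            "bootstrap": list(self.bootstrap),
        }


@dataclass
class EvaluationReport:
    """ROC/PR curves with summary areas and selected operating thresholds."""

    roc: list[tuple[float, float, float]]  # (FPR, TPR, threshold)
    pr: list[tuple[float, float, float]]  # (recall, precision, threshold)
    auroc: float
    average_precision: float
    thresholds: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def build_difference_features(
    pairs: Sequence[tuple[str, str]],
    model: EmbeddingModel,
    pk_token_map: Mapping[str, str],
    cancer_token_map: Mapping[str, str],
    labels: Mapping[tuple[str, str], int] | None = None,
) -> list[FeatureRow]:
    """Difference vectors f(pk) - f(cancer) for resolvable pairs.

    Token maps translate PK symbols and cancer MeSH ids to their corpus
    concept tokens.  Pairs whose tokens are unresolvable or out of
    vocabulary are dropped with a log entry; an empty result is an error.
    """
    rows = []
    dropped = 0
    for pk, cancer in sorted(set(pairs)):
        pk_tok = pk_token_map.get(pk)
        ca_tok = cancer_token_map.get(cancer)
        if pk_tok is None or ca_tok is None or pk_tok not in model or ca_tok not in model:
            dropped += 1
            logger.debug("dropping pair (%s, %s): token missing from embedding", pk, cancer)
            continue
        v = model.vector(pk_tok) - model.vector(ca_tok)
        label = labels.get((pk, cancer)) if labels is not None else None
        rows.append(FeatureRow(pk, cancer, v, label))
    if dropped:
        logger.info("dropped %d/%d pairs lacking embedding vectors", dropped, len(set(pairs)))
    if not rows:
        raise ClassifierError("no pair could be featurized: all tokens missing from embedding")
    return rows


def _matrix(rows: Sequence[FeatureRow]) -> np.ndarray:
    return np.vstack([r.v for r in rows])


def _labels(rows: Sequence[FeatureRow]) -> np.ndarray:
    return np.array([r.label for r in rows], dtype=int)


# ---------------------------------------------------------------------------
# Training and scoring
# ---------------------------------------------------------------------------

def train_classifier(
    train_rows: Sequence[FeatureRow], space: SearchSpace = SearchSpace()
) -> RandomizedSearchCV:
    """Randomized hyperparameter search + refit of the best random forest.

    ``iterations`` configurations are sampled from the space (without
    replacement when the space is finite and small), each scored by
    ``cv_folds``-fold cross-validated AUROC; the best is refitted on all
    training rows.  Fully reproducible for a fixed seed.
    """
    X, y = _matrix(train_rows), _labels(train_rows)
    if len(np.unique(y)) < 2:
        raise ClassifierError("training rows contain a single class")
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=space.seed, n_jobs=1),
        param_distributions=space.param_distributions,
        n_iter=space.iterations,
        cv=space.cv_folds,
        scoring="roc_auc",
        random_state=space.seed,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    return search


def score_pairs(model, rows: Sequence[FeatureRow]) -> np.ndarray:
    """Positive-class probability (tree-vote fraction) per row, order kept."""
    X = _matrix(rows)
    est = model.best_estimator_ if hasattr(model, "best_estimator_") else model
    if X.shape[1] != est.n_features_in_:
        raise ClassifierError(
            f"feature dimension {X.shape[1]} does not match model ({est.n_features_in_})"
        )
    return est.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(scores: Sequence[float], labels: Sequence[int]) -> EvaluationReport:
    """ROC/PR curves by threshold sweep, AUROC by trapezoid, AP by step sum."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ClassifierError("evaluation needs both classes present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    auroc = float(roc_auc_score(labels, scores))
    ap = float(average_precision_score(labels, scores))
    roc = list(zip(fpr.tolist(), tpr.tolist(), roc_thr.tolist()))
    # precision_recall_curve returns curves ending at recall 0 with no
    # threshold for the final point; keep (recall, precision, threshold).
    pr = list(zip(recall[:-1].tolist(), precision[:-1].tolist(), pr_thr.tolist()))
    report = EvaluationReport(roc=roc, pr=pr, auroc=auroc, average_precision=ap)
    report.thresholds = {
        "gmean": select_threshold(scores, labels, "gmean"),
        "f1_opt": select_threshold(scores, labels, "f1_opt"),
    }
    return report


def _confusion_at(scores: np.ndarray, labels: np.ndarray, thr: float):
    pred = scores >= thr
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def select_threshold(scores, labels, criterion: str = "gmean") -> float:
    """Best operating threshold over all distinct scores.

    ``gmean`` maximizes sqrt(TPR * (1 - FPR)); ``f1_opt`` maximizes the F1
    score.  The decision rule is ``score >= threshold``; ties are broken
    toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    best_thr, best_val = None, -1.0
    for thr in sorted(np.unique(scores)):
        tp, fp, fn, tn = _confusion_at(scores, labels, thr)
        if criterion == "gmean":
            tprate = tp / (tp + fn) if tp + fn else 0.0
            fprate = fp / (fp + tn) if fp + tn else 0.0
            val = math.sqrt(tprate * (1.0 - fprate))
        elif criterion == "f1_opt":
            val = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        else:
            raise ClassifierError(f"unknown threshold criterion {criterion!r}")
        if val > best_val + 1e-12:
            best_val, best_thr = val, float(thr)
    return best_thr


def rank_predictions(
    model, universe_rows: Sequence[FeatureRow], threshold: float
) -> list[dict]:
    """Universe pairs ranked by descending score; ties by (pk, cancer).

    Each entry carries rank (1-based), pk, cancer, score and the
    above-threshold flag (score >= threshold).
    """
    scores = score_pairs(model, universe_rows)
    order = sorted(
        range(len(universe_rows)),
        key=lambda i: (-scores[i], universe_rows[i].pk, universe_rows[i].cancer),
    )
    return [
        {
            "rank": rank,
            "pk": universe_rows[i].pk,
            "cancer": universe_rows[i].cancer,
            "score": float(scores[i]),
            "above_threshold": bool(scores[i] >= threshold),
        }
        for rank, i in enumerate(order, 1)
    ]


def permutation_control_auroc(
    scores: Sequence[float], labels: Sequence[int], n_permutations: int = 20, seed: int = 0
) -> float:
    """Mean AUROC of the scores against shuffled labels (null control ~0.5)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    vals = []
    for _ in range(n_permutations):
        vals.append(roc_auc_score(rng.permutation(labels), scores))
    return float(np.mean(vals))
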