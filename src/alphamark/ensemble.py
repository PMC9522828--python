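"""Two-level stacked classifier over the four marker profiles.

Level 1 fits one linear SVM (L2 penalty, C = 1, per-feature standardization)
per marker type; level 2 is a 2000-tree random forest over the stacked
level-1 decision scores. For tissue-of-origin (TOO) prediction both levels
are one-vs-rest multiclass. To keep level 2 from learning level-1
training-set optimism, the forest is trained on cross-fitted (out-of-fold)
level-1 scores: each training sample's level-1 output comes from a model
that never saw it.

Detection outputs the forest's cancer probability; TOO outputs per-class
membership probabilities plus a confidence gate — the fold change between
the top two probabilities must reach 2.5 for a call to be made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .profiles import MARKER_TYPES

DEFAULT_C = 1.0
DEFAULT_N_TREES = 2000
DEFAULT_K_FOLDS = 5
DEFAULT_CONFIDENCE_THRESHOLD = 2.5


@dataclass
class TOOPrediction:
    """Tissue-of-origin call with its fold-change confidence."""

    probs: dict[str, float]
    top_type: str
    confidence: float
    call: str | None

    @classmethod
    def from_probs(cls, probs: Mapping[str, float],
                   threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> "TOOPrediction":
        items = sorted(probs.items(), key=lambda kv: -kv[1])
        p1, p2 = items[0][1], items[1][1]
        confidence = float("inf") if p2 == 0 else p1 / p2
        call = items[0][0] if confidence >= threshold else None
        return cls(dict(probs), items[0][0], confidence, call)


def _make_level1(task: str, seed: int, C: float = DEFAULT_C) -> Pipeline:
    svm = LinearSVC(C=C, penalty="l2", dual=True, random_state=seed, max_iter=20000)
    clf = OneVsRestClassifier(svm) if task == "too" else svm
    return Pipeline([("scale", StandardScaler()), ("svm", clf)])


def _scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    s = model.decision_function(X)
    return s[:, None] if s.ndim == 1 else s


def train_level1(X: np.ndarray, y: Sequence, task: str = "detection", seed: int = 0) -> Pipeline:
    """Fit the per-view linear SVM (one-vs-rest when task='too')."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("level-1 training requires at least two classes")
    model = _make_level1(task, seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def cross_fit_level1(
    X: np.ndarray, y: Sequence, task: str = "detection",
    k_folds: int = DEFAULT_K_FOLDS, seed: int = 0,
) -> np.ndarray:
    """Out-of-fold level-1 decision scores for every training sample.

    Stratified k-fold; if the rarest class has fewer members than k, the
    fold count is reduced with a warning (never below 2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k = min(k_folds, counts.min())
    if k < k_folds:
        warnings.warn(f"reducing folds from {k_folds} to {k}: smallest class has {counts.min()} members")
    if k < 2:
        raise ValueError("cross-fitting requires every class to have >=2 members")
    out: np.ndarray | None = None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        model = _make_level1(task, seed)
        model.fit(X[train_idx], y[train_idx])
        s = _scores(model, X[test_idx])
        if out is None:
            out = np.zeros((len(y), s.shape[1]))
        out[test_idx] = s
    return out


@dataclass
class StackedModel:
    """Four level-1 linear SVMs + level-2 random forest."""

    task: str                              # detection | too
    classes: list
    level1: dict[str, Pipeline]
    forest: object
    panel_hashes: dict[str, str]
    seed: int
    config: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str) -> "StackedModel":
        return joblib.load(path)


def _check_views(profiles: Mapping[str, pd.DataFrame]) -> list[str]:
    missing = [t for t in MARKER_TYPES if t not in profiles]
    if missing:
        raise ValueError(f"missing profile views: {missing}")
    index = profiles[MARKER_TYPES[0]].index
    for t in MARKER_TYPES[1:]:
        if not profiles[t].index.equals(index):
            raise ValueError("the four profile views must cover identical samples in order")
    return list(index)


def train_stacked(
    profiles: Mapping[str, pd.DataFrame],
    labels: Mapping[str, object] | pd.Series,
    task: str = "detection",
    seed: int = 0,
    k_folds: int = DEFAULT_K_FOLDS,
    n_trees: int = DEFAULT_N_TREES,
    C: float = DEFAULT_C,
) -> StackedModel:
    """Fit the full stacked model.

    Level-1 models are fitted on all training samples; the level-2 forest is
    fitted on their cross-fitted out-of-fold scores (detection: one score
    per view; TOO: one one-vs-rest score per class per view).
    """
    sample_ids = _check_views(profiles)
    y = np.asarray(pd.Series(labels).reindex(sample_ids))
    if pd.isna(y).any():
        raise ValueError("labels missing for some samples")
    level1: dict[str, Pipeline] = {}
    oof_blocks = []
    for t in MARKER_TYPES:
        X = profiles[t].to_numpy(dtype=float)
        level1[t] = train_level1(X, y, task, seed)
        oof_blocks.append(cross_fit_level1(X, y, task, k_folds, seed))
    Z = np.hstack(oof_blocks)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest = OneVsRestClassifier(rf) if task == "too" else rf
    forest.fit(Z, y)
    return StackedModel(
        task=task,
        classes=list(np.unique(y)),
        level1=level1,
        forest=forest,
        panel_hashes={t: profiles[t].attrs.get("panel_hash", "") for t in MARKER_TYPES},
        seed=seed,
        config={"k_folds": k_folds, "n_trees": n_trees, "C": C},
    )


def _stack_features(model: StackedModel, profiles: Mapping[str, pd.DataFrame]) -> np.ndarray:
    _check_views(profiles)
    for t in MARKER_TYPES:
        h = profiles[t].attrs.get("panel_hash", "")
        if model.panel_hashes.get(t) and h and h != model.panel_hashes[t]:
            raise ValueError(f"panel hash mismatch for {t}: profiles were built on a different panel")
    return np.hstack([_scores(model.level1[t], profiles[t].to_numpy(dtype=float)) for t in MARKER_TYPES])


def level1_scores(model: StackedModel, profiles: Mapping[str, pd.DataFrame]) -> dict[str, np.ndarray]:
    """Per-view level-1 decision scores (diagnostics and per-view baselines)."""
    _check_views(profiles)
    return {t: _scores(model.level1[t], profiles[t].to_numpy(dtype=float)) for t in MARKER_TYPES}


def predict_detection(model: StackedModel, profiles: Mapping[str, pd.DataFrame]) -> np.ndarray:
    """Cancer probability per sample; thresholding is left to the evaluator."""
    if model.task != "detection":
        raise ValueError("model was not trained for detection")
    Z = _stack_features(model, profiles)
    proba = model.forest.predict_proba(Z)
    classes = list(model.forest.classes_)
    if "cancer" in classes:
        cancer_col = classes.index("cancer")
    elif 1 in classes:
        cancer_col = classes.index(1)
    else:
        cancer_col = len(classes) - 1
    return proba[:, cancer_col]


def predict_too(
    model: StackedModel,
    profiles: Mapping[str, pd.DataFrame],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[TOOPrediction]:
    """Per-sample tissue-of-origin membership probabilities and gated calls."""
    if model.task != "too":
        raise ValueError("model was not trained for TOO prediction")
    if len(model.classes) < 2:
        raise ValueError("TOO prediction requires at least two classes")
    Z = _stack_features(model, profiles)
    proba = model.forest.predict_proba(Z)
    # one-vs-rest probabilities are renormalized to sum to 1 per sample
    total = proba.sum(axis=1, keepdims=True)
    proba = np.where(total > 0, proba / np.where(total == 0, 1.0, total), 1.0 / proba.shape[1])
    classes = list(model.forest.classes_)
    return [
        TOOPrediction.from_probs(dict(zip(classes, row)), confidence_threshold)
        for row in proba
    ]
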