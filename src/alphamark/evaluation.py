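"""Random-split validation protocol and performance metrics.

Each run randomly holds out 25% of cancer and 25% of noncancer plasma
samples for testing, reserves 30 noncancer samples from the remaining 75%
solely for marker filtration (the reference plasma panel), and trains on
the rest. The protocol is repeated (default 10 runs) and metrics are
summarized as the mean with a 95% interval across runs.

Metrics: AUROC; sensitivity at a fixed number of false positives (the
paper-style "sensitivity at 1 false positive", i.e. the ROC operating point
just above the (n_fp+1)-th highest negative score); TOO accuracy over
called samples; per-type precision; confusion matrices accumulated across
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ensemble import TOOPrediction

DEFAULT_N_RUNS = 10
DEFAULT_TEST_FRAC = 0.25
DEFAULT_RESERVE = 30


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitPlan:
    run_index: int
    train_ids: list[str]
    test_ids: list[str]
    reference_ids: list[str]
    seed: int


def make_splits(
    meta: pd.DataFrame,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    test_frac: float = DEFAULT_TEST_FRAC,
    reserve: int = DEFAULT_RESERVE,
) -> list[SplitPlan]:
    """Seeded random-split plans over the plasma cohort.

    Per run: ``round_half_up(test_frac * n)`` samples of each class go to
    the test set; ``reserve`` noncancer samples are drawn from the remaining
    noncancer pool for marker filtration only; everything else trains.
    Round-half-up keeps the canonical cohort arithmetic (e.g. 191 noncancer
    -> 48 test, so one false positive is 97.9% specificity).
    """
    plasma = meta[meta["material"] == "plasma"]
    cancer_ids = plasma.loc[plasma["condition"] == "cancer", "sample_id"].to_numpy()
    noncancer_ids = plasma.loc[plasma["condition"] == "noncancer", "sample_id"].to_numpy()
    if len(cancer_ids) == 0 or len(noncancer_ids) == 0:
        raise ValueError("cohort must contain both cancer and noncancer plasma samples")
    n_test_cancer = round_half_up(test_frac * len(cancer_ids))
    n_test_noncancer = round_half_up(test_frac * len(noncancer_ids))
    if len(noncancer_ids) - n_test_noncancer < reserve:
        raise ValueError(
            f"cannot reserve {reserve} noncancer samples: only "
            f"{len(noncancer_ids) - n_test_noncancer} outside the test set"
        )
    plans = []
    root = np.random.SeedSequence(seed)
    for run, child in enumerate(root.spawn(n_runs)):
        rng = np.random.default_rng(child)
        test_c = rng.choice(cancer_ids, n_test_cancer, replace=False)
        test_n = rng.choice(noncancer_ids, n_test_noncancer, replace=False)
        pool_n = np.setdiff1d(noncancer_ids, test_n)
        ref_n = rng.choice(pool_n, reserve, replace=False)
        train = np.concatenate([
            np.setdiff1d(cancer_ids, test_c),
            np.setdiff1d(pool_n, ref_n),
        ])
        plans.append(SplitPlan(run, sorted(train), sorted(np.concatenate([test_c, test_n])),
                               sorted(ref_n), seed))
    return plans


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals P(score_pos > score_neg) + P(tie)/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float
    n_fp_achieved: int


def sensitivity_at_fp(scores: Sequence[float], labels: Sequence[int], n_fp: int = 1) -> OperatingPoint:
    """Sensitivity at the ROC operating point admitting at most ``n_fp`` false positives.

    The threshold sits just above the (n_fp+1)-th highest negative score, so
    exactly n_fp negatives (fewer under ties) score at or above it;
    sensitivity is the fraction of positives at or above the threshold.
    With tie-free negatives, specificity is exactly 1 - n_fp/#negatives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    neg = np.sort(scores[labels == 0])[::-1]
    pos = scores[labels == 1]
    if len(neg) < n_fp + 1:
        raise ValueError(f"need at least {n_fp + 1} negatives")
    boundary = neg[n_fp]
    above = scores[scores > boundary]
    threshold = (boundary + above.min()) / 2 if len(above) else boundary + 1.0
    n_fp_achieved = int(np.count_nonzero(neg >= threshold))
    sensitivity = float(np.count_nonzero(pos >= threshold) / len(pos)) if len(pos) else 0.0
    specificity = 1.0 - n_fp_achieved / len(neg)
    return OperatingPoint(sensitivity, specificity, float(threshold), n_fp_achieved)


@dataclass
class TOOMetrics:
    accuracy: float | None
    precision: dict[str, float]
    confusion: pd.DataFrame
    n_called: int
    n_no_call: int


def too_metrics(predictions: Sequence[TOOPrediction], truth: Sequence[str],
                classes: Sequence[str] | None = None) -> TOOMetrics:
    """Accuracy over called samples, per-type precision, and the confusion matrix.

    Accuracy = correctly predicted / total called; precision(type) =
    correctly predicted as type / total predicted as type. With zero called
    samples, accuracy is None (flagged undefined).
    """
    if classes is None:
        classes = sorted(set(truth))
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    n_no_call = 0
    for pred, t in zip(predictions, truth):
        if pred.call is None:
            n_no_call += 1
            continue
        conf.loc[t, pred.call] += 1
    n_called = int(conf.to_numpy().sum())
    accuracy = float(np.trace(conf.to_numpy()) / n_called) if n_called else None
    precision = {}
    for c in classes:
        n_pred = int(conf[c].sum())
        if n_pred:
            precision[c] = float(conf.loc[c, c] / n_pred)
    return TOOMetrics(accuracy, precision, conf, n_called, n_no_call)


def accumulate_confusions(metrics: Sequence[TOOMetrics]) -> pd.DataFrame:
    """Sum confusion matrices across runs (rows: truth, columns: prediction)."""
    total = metrics[0].confusion.copy()
    for m in metrics[1:]:
        total = total.add(m.confusion, fill_value=0).astype(int)
    return total


def summarize_runs(
    run_metrics: Sequence[Mapping[str, float]],
    ci_method: str = "percentile",
) -> pd.DataFrame:
    """Mean and 95% interval per metric across runs.

    ``percentile`` uses the 2.5/97.5 empirical percentiles;
    ``normal`` uses mean +/- 1.96 * sd.
    """
    if len(run_metrics) < 2:
        raise ValueError("summarize_runs needs at least 2 runs")
    df = pd.DataFrame(run_metrics)
    rows = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            rows[col] = (np.nan, np.nan, np.nan)
            continue
        mean = vals.mean()
        if ci_method == "percentile":
            lo, hi = np.percentile(vals, [2.5, 97.5])
        elif ci_method == "normal":
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        rows[col] = (mean, lo, hi)
    return pd.DataFrame(rows, index=["mean", "ci_low", "ci_high"]).T


def sensitivity_by_group(
    scores: Sequence[float], labels: Sequence[int], groups: Sequence[str | None],
    threshold: float,
) -> dict[str, float]:
    """Per-group (stage or cancer type) sensitivity at a fixed score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    for g in sorted({g for g, l in zip(groups, labels) if l == 1 and g is not None}):
        mask = (labels == 1) & (np.asarray(groups, dtype=object) == g)
        out[g] = float(np.count_nonzero(scores[mask] >= threshold) / mask.sum())
    return out
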