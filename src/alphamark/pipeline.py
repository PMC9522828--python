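"""End-to-end random-split protocol: discovery, profiling, training, scoring.

Per run: marker panels are re-derived using the run's reserved reference
plasma (the reference draw changes across runs, so panels differ slightly);
train/test plasma samples are profiled against the run's panels; the
detection model is trained cancer-vs-noncancer and the TOO model
one-vs-rest on training cancer samples; metrics are computed on the held-out
test set and summarized across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    DEFAULT_K_FOLDS,
    DEFAULT_N_TREES,
    level1_scores,
    predict_detection,
    predict_too,
    train_stacked,
)
from .evaluation import (
    DEFAULT_N_RUNS,
    DEFAULT_RESERVE,
    SplitPlan,
    TOOMetrics,
    accumulate_confusions,
    auroc,
    make_splits,
    sensitivity_at_fp,
    summarize_runs,
    too_metrics,
)
from .markers import DiscoveryParams, MarkerSet, build_marker_panels
from .profiles import MARKER_TYPES, build_profile_matrix
from .read_io import AlphaDistribution, build_distributions, raw_read_counts
from .regions import RegionIndex
from .simulate import Cohort

logger = logging.getLogger(__name__)


@dataclass
class ProtocolParams:
    n_runs: int = DEFAULT_N_RUNS
    test_frac: float = 0.25
    reserve: int = DEFAULT_RESERVE
    n_trees: int = DEFAULT_N_TREES
    k_folds: int = DEFAULT_K_FOLDS
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    n_fp: int = 1
    min_cpg: int = 3


@dataclass
class RunResult:
    run_index: int
    metrics: dict[str, float]
    too: TOOMetrics | None
    panels: dict[str, dict[str, MarkerSet]]
    detection_scores: pd.Series
    level1_aurocs: dict[str, float]


@dataclass
class ProtocolResult:
    runs: list[RunResult]
    summary: pd.DataFrame
    confusion: pd.DataFrame

    def run_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.metrics for r in self.runs])


def cohort_distributions(cohort: Cohort, min_cpg: int = 3):
    index = RegionIndex(cohort.regions)
    dists, summary = build_distributions(cohort.reads, index, min_cpg=min_cpg)
    return dists, summary


def run_one_split(
    dists: Mapping[tuple[str, str], AlphaDistribution],
    meta: pd.DataFrame,
    region_ids: Sequence[str],
    plan: SplitPlan,
    discovery: DiscoveryParams,
    protocol: ProtocolParams,
    seed: int,
    tasks: Sequence[str] = ("detection", "too"),
) -> RunResult:
    """Discovery + training + test-set evaluation for one split plan."""
    raw = raw_read_counts(meta)
    panels = build_marker_panels(
        dists, meta, region_ids, discovery, seed=seed, reference_ids=plan.reference_ids,
        tasks=tasks,
    )
    plasma = meta.set_index("sample_id")
    train_ids, test_ids = plan.train_ids, plan.test_ids

    def profile_views(task: str, sample_ids: Sequence[str]) -> dict[str, pd.DataFrame]:
        return {
            t: build_profile_matrix(dists, sample_ids, panels[task][t], raw, t)
            for t in MARKER_TYPES
        }

    # --- detection ---
    y_train = (plasma.loc[train_ids, "condition"] == "cancer").astype(int)
    y_test = (plasma.loc[test_ids, "condition"] == "cancer").astype(int)
    det_model = train_stacked(
        profile_views("detection", train_ids), y_train, task="detection",
        seed=seed, k_folds=protocol.k_folds, n_trees=protocol.n_trees,
    )
    test_views = profile_views("detection", test_ids)
    scores = predict_detection(det_model, test_views)
    op = sensitivity_at_fp(scores, y_test.to_numpy(), n_fp=protocol.n_fp)
    l1_aurocs = {
        t: auroc(s[:, 0], y_test.to_numpy())
        for t, s in level1_scores(det_model, test_views).items()
    }

    # --- tissue of origin (cancer test samples only) ---
    tm = None
    metrics = {
        "auroc": auroc(scores, y_test.to_numpy()),
        "sensitivity_at_1fp": op.sensitivity,
        "specificity": op.specificity,
    }
    if "too" in tasks:
        train_cancer = [s for s in train_ids if plasma.loc[s, "condition"] == "cancer"]
        test_cancer = [s for s in test_ids if plasma.loc[s, "condition"] == "cancer"]
        too_model = train_stacked(
            profile_views("too", train_cancer), plasma.loc[train_cancer, "tissue"], task="too",
            seed=seed, k_folds=protocol.k_folds, n_trees=protocol.n_trees,
        )
        preds = predict_too(too_model, profile_views("too", test_cancer),
                            protocol.confidence_threshold)
        tm = too_metrics(preds, plasma.loc[test_cancer, "tissue"].tolist(),
                         classes=sorted(plasma.loc[plasma["condition"] == "cancer", "tissue"].unique()))
        metrics["too_accuracy"] = np.nan if tm.accuracy is None else tm.accuracy
        metrics["too_no_call_frac"] = tm.n_no_call / max(len(preds), 1)
    metrics.update({f"auroc_{t}": v for t, v in l1_aurocs.items()})
    logger.info("run %d: %s", plan.run_index, {k: round(v, 4) for k, v in metrics.items()})
    return RunResult(plan.run_index, metrics, tm, panels,
                     pd.Series(scores, index=test_ids), l1_aurocs)


def detection_experiment(
    cohort: Cohort,
    seed: int,
    discovery: DiscoveryParams | None = None,
    protocol: ProtocolParams | None = None,
    test_frac: float = 0.5,
) -> float:
    """Single-split, detection-only test AUROC for one cohort.

    Used for dose-response experiments (e.g. detection power as a function
    of tumor fraction), where a large held-out test half keeps the AUROC
    estimate stable.
    """
    discovery = discovery or DiscoveryParams()
    protocol = protocol or ProtocolParams()
    dists, _ = cohort_distributions(cohort, min_cpg=protocol.min_cpg)
    region_ids = [r.region_id for r in cohort.regions]
    plan = make_splits(cohort.meta, n_runs=1, seed=seed, test_frac=test_frac,
                       reserve=protocol.reserve)[0]
    result = run_one_split(dists, cohort.meta, region_ids, plan, discovery, protocol,
                           seed=seed, tasks=("detection",))
    return result.metrics["auroc"]


def run_protocol(
    cohort: Cohort,
    discovery: DiscoveryParams | None = None,
    protocol: ProtocolParams | None = None,
    seed: int = 0,
) -> ProtocolResult:
    """The full repeated random-split validation on a cohort."""
    discovery = discovery or DiscoveryParams()
    protocol = protocol or ProtocolParams()
    dists, _ = cohort_distributions(cohort, min_cpg=protocol.min_cpg)
    region_ids = [r.region_id for r in cohort.regions]
    plans = make_splits(cohort.meta, n_runs=protocol.n_runs, seed=seed,
                        test_frac=protocol.test_frac, reserve=protocol.reserve)
    runs = [
        run_one_split(dists, cohort.meta, region_ids, plan, discovery, protocol,
                      seed=seed + plan.run_index)
        for plan in plans
    ]
    summary = summarize_runs([r.metrics for r in runs])
    confusion = accumulate_confusions([r.too for r in runs])
    return ProtocolResult(runs, summary, confusion)
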