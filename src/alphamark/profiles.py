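"""Marker profiles: normalized, log-transformed directional read counts.

For every marker in a panel, the sample's reads in that region with alpha
past the marker's learned threshold are counted, depth-normalized by the
sample's total mapped fragment count, and log-transformed:

    value = ln(1e9 * count / raw_total + 1)

The values over a panel, in panel order, form one feature profile; the four
panels give the four profiles consumed by the stacked classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markers import MarkerSet, directional_count
from .read_io import AlphaDistribution

MARKER_TYPES = ("cancer_hyper", "cancer_hypo", "tissue_hyper", "tissue_hypo")


@dataclass
class FeatureProfile:
    sample_id: str
    marker_type: str
    values: np.ndarray
    panel_hash: str


def profile_value(count: int | np.ndarray, raw_total: int) -> float | np.ndarray:
    """ln(1e9 * count / raw_total + 1); invariant under joint count/depth rescaling."""
    if raw_total <= 0:
        raise ValueError(f"raw_total must be positive, got {raw_total}")
    if np.any(np.asarray(count) < 0):
        raise ValueError("count must be non-negative")
    out = np.log1p(1e9 * np.asarray(count, dtype=float) / raw_total)
    return float(out) if np.isscalar(count) else out


def build_profile(
    dists: Mapping[tuple[str, str], AlphaDistribution],
    sample_id: str,
    marker_set: MarkerSet,
    raw_total: int,
    marker_type: str = "",
) -> FeatureProfile:
    """One sample's profile over a marker panel, each marker at its own threshold."""
    counts = np.zeros(len(marker_set), dtype=float)
    for j, m in enumerate(marker_set.markers):
        d = dists.get((m.region_id, sample_id))
        if d is not None:
            counts[j] = directional_count(d, m.alpha_thr, m.direction)
    return FeatureProfile(sample_id, marker_type, profile_value(counts, raw_total), marker_set.panel_hash())


def build_profile_matrix(
    dists: Mapping[tuple[str, str], AlphaDistribution],
    sample_ids: Sequence[str],
    marker_set: MarkerSet,
    raw_totals: Mapping[str, int],
    marker_type: str = "",
) -> pd.DataFrame:
    """Samples x markers profile matrix; the panel hash rides in ``df.attrs``."""
    mat = np.vstack(
        [build_profile(dists, s, marker_set, raw_totals[s], marker_type).values for s in sample_ids]
    ) if len(marker_set) else np.zeros((len(sample_ids), 0))
    df = pd.DataFrame(mat, index=list(sample_ids), columns=marker_set.region_ids)
    df.attrs["panel_hash"] = marker_set.panel_hash()
    df.attrs["marker_type"] = marker_type
    return df


def write_profile_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_profile_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
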