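"""Per-read methylation records, alpha-values, and per-region alpha distributions.

The alpha-value of a sequenced fragment is the fraction of methylated CpGs
among all CpG sites the fragment covers. Unlike the population-average
beta-value, it is a read-level statistic: a handful of fully methylated
tumor-derived fragments stands out in a region even when the bulk of the
sample is unmethylated. Reads covering fewer than ``min_cpg`` CpG sites are
excluded from alpha analyses (defaults to 3; one or two CpGs make alpha
quasi-binary noise).

The canonical interchange format is a TSV with columns
``sample_id, chrom, start, end, n_cpg_meth, n_cpg_total`` — one row per
deduplicated fragment (mate pairs already merged), gzip-capable. Alignment
and methylation calling upstream of this table are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .regions import Region, RegionIndex

logger = logging.getLogger(__name__)

READ_COLUMNS = ["sample_id", "chrom", "start", "end", "n_cpg_meth", "n_cpg_total"]

META_COLUMNS = [
    "sample_id",
    "material",       # tissue | plasma
    "tissue",         # colon | liver | lung | stomach | ...
    "condition",      # tissue: tumor | adjacent_normal | normal ; plasma: cancer | noncancer
    "pair_id",        # links tumor to its adjacent normal (tissue pairs only)
    "stage",          # optional tumor stage
    "cohort_role",    # discovery | reference_plasma | train | test (may be set per run)
    "raw_read_count",  # total mapped deduplicated fragments in the sample
]

DEFAULT_MIN_CPG = 3


@dataclass(frozen=True)
class MethRead:
    """One fragment's CpG methylation summary."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_cpg_meth: int
    n_cpg_total: int


@dataclass
class AlphaDistribution:
    """Multiset of per-read alpha-values for one (region, sample)."""

    region_id: str
    sample_id: str
    alphas: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.alphas)


@dataclass
class BuildSummary:
    """Read accounting for build_distributions; conserves the parsed total."""

    n_included: int = 0
    n_excluded_low_cpg: int = 0
    n_outside_region: int = 0

    @property
    def n_total(self) -> int:
        return self.n_included + self.n_excluded_low_cpg + self.n_outside_region


def alpha_value(read: MethRead, min_cpg: int = DEFAULT_MIN_CPG) -> float | None:
    """Fraction of methylated CpGs in the read, or None when below the CpG floor."""
    if read.n_cpg_total < max(min_cpg, 1):
        return None
    return read.n_cpg_meth / read.n_cpg_total


def read_reads_table(path: str) -> tuple[pd.DataFrame, int]:
    """Load and validate the canonical read TSV.

    Returns (valid records in file order, number of rejected records).
    Records with ``n_cpg_meth > n_cpg_total``, negative counts, or
    ``end <= start`` are rejected and logged; a missing column is a format
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table {path!r} missing columns: {missing}")
    df = df[READ_COLUMNS]
    bad = (
        (df["n_cpg_meth"] > df["n_cpg_total"])
        | (df["n_cpg_meth"] < 0)
        | (df["n_cpg_total"] < 0)
        | (df["end"] <= df["start"])
    )
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning("%d malformed read records rejected from %s", n_rejected, path)
    return df.loc[~bad].reset_index(drop=True), n_rejected


def parse_reads(path: str) -> Iterator[MethRead]:
    """Stream validated MethRead records from the canonical TSV."""
    df, _ = read_reads_table(path)
    for row in df.itertuples(index=False):
        yield MethRead(row.sample_id, row.chrom, int(row.start), int(row.end),
                       int(row.n_cpg_meth), int(row.n_cpg_total))


def write_reads_table(reads: pd.DataFrame, path: str) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def build_distributions(
    reads: pd.DataFrame | Iterable[MethRead],
    regions: RegionIndex | Iterable[Region],
    min_cpg: int = DEFAULT_MIN_CPG,
) -> tuple[dict[tuple[str, str], AlphaDistribution], BuildSummary]:
    """Group read alpha-values into per-(region, sample) distributions.

    Each read that passes the CpG floor contributes exactly one alpha-value
    to the region containing its midpoint; reads below the floor or outside
    every region are tallied in the summary.
    """
    if not isinstance(regions, RegionIndex):
        regions = RegionIndex(regions)
    if not isinstance(reads, pd.DataFrame):
        reads = pd.DataFrame(
            [(r.sample_id, r.chrom, r.start, r.end, r.n_cpg_meth, r.n_cpg_total) for r in reads],
            columns=READ_COLUMNS,
        )
    summary = BuildSummary()
    dists: dict[tuple[str, str], AlphaDistribution] = {}
    if reads.empty:
        return dists, summary

    floor = max(min_cpg, 1)
    pass_cpg = reads["n_cpg_total"].to_numpy() >= floor
    summary.n_excluded_low_cpg = int((~pass_cpg).sum())
    kept = reads.loc[pass_cpg]
    region_ids = regions.assign_many(
        kept["chrom"].to_numpy(), kept["start"].to_numpy(), kept["end"].to_numpy()
    )
    region_arr = np.asarray(region_ids, dtype=object)
    inside = region_arr != None  # noqa: E711  (element-wise against object array)
    summary.n_outside_region = int((~inside).sum())
    summary.n_included = int(inside.sum())

    kept = kept.loc[inside]
    alphas = kept["n_cpg_meth"].to_numpy(dtype=float) / kept["n_cpg_total"].to_numpy(dtype=float)
    grouped = pd.DataFrame(
        {"region_id": region_arr[inside], "sample_id": kept["sample_id"].to_numpy(), "alpha": alphas}
    ).groupby(["region_id", "sample_id"], sort=False)
    for (region_id, sample_id), grp in grouped:
        dists[(region_id, sample_id)] = AlphaDistribution(
            region_id, sample_id, grp["alpha"].to_numpy()
        )
    return dists, summary


def read_sample_metadata(path: str) -> pd.DataFrame:
    """Load the sample metadata TSV, validating required columns and pairing."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pair_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path!r} missing columns: {missing}")
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame) -> None:
    if (meta["raw_read_count"] <= 0).any():
        raise ValueError("raw_read_count must be positive for every sample")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    paired = meta["condition"].isin(["tumor", "adjacent_normal"]) & (meta["material"] == "tissue")
    if meta.loc[paired, "pair_id"].isna().any():
        raise ValueError("tumor/adjacent_normal tissue samples require a pair_id")


def write_sample_metadata(meta: pd.DataFrame, path: str) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def raw_read_counts(meta: pd.DataFrame) -> Mapping[str, int]:
    return dict(zip(meta["sample_id"], meta["raw_read_count"].astype(int)))
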