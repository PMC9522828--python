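"""Synthetic methylomes: references, tissues with planted DMRs, plasma mixtures.

The generator emulates the data structures the discovery and classification
machinery assumes, at desk scale:

- a toy reference whose CCGG placements digest into an exact, known set of
  unit regions, each with a chosen CpG count;
- per-class regional methylation levels with planted differentially
  methylated regions (DMRs): pan-cancer DMRs shared by every tumor type
  (cancer detection signal), tumor-type-specific DMRs (tissue-of-origin
  signal), and tissue-specific DMRs separating normal tissues;
- reads drawn with molecule-level heterogeneity: a fragment's methylation
  propensity m* ~ Beta(m*kappa, (1-m)*kappa) around the region-class level
  m, and its methylated CpG count ~ Binomial(n_cpg, m*). Small kappa gives
  the bimodal, heterogeneous alpha-value distributions read-level discovery
  exploits;
- plasma samples as read mixtures: each fragment is tumor-derived with
  probability equal to the tumor fraction, otherwise drawn from a weighted
  blend of normal-tissue methylomes (the cfDNA background).

Sequencing error, bisulfite non-conversion, and fragment-length variation
are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .read_io import META_COLUMNS, READ_COLUMNS
from .regions import Region, digest_regions

CHROM = "sim1"


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    n_regions: int = 200
    cpg_range: tuple[int, int] = (3, 8)
    cancer_types: tuple[str, ...] = ("colon", "liver", "lung", "stomach")
    n_pairs_per_type: int = 20
    n_normals_per_tissue: int = 8
    n_cancer_plasma_per_type: int = 15
    n_noncancer_plasma: int = 60
    depth: int = 30                      # reads per region per sample
    kappa: float = 5.0                   # molecule-heterogeneity concentration
    tumor_fraction: float = 0.1          # tumor-derived fragment fraction in cancer plasma
    tumor_purity: float = 0.7            # tumor-cell fraction in tumor tissue samples
    delta: float = 0.6                   # planted DMR methylation shift
    n_shared_hyper: int = 10             # pan-cancer DMRs (detection)
    n_shared_hypo: int = 10
    n_type_hyper: int = 3                # per cancer type (TOO)
    n_type_hypo: int = 3
    n_tissue_hyper: int = 3              # per tissue (tissue panels)
    n_tissue_hypo: int = 3
    background_weights: Mapping[str, float] | None = None  # default: liver-weighted blend

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if not 0.0 < self.delta <= 0.9:
            raise ValueError("delta must be in (0, 0.9]")
        n_planted = (self.n_shared_hyper + self.n_shared_hypo
                     + len(self.cancer_types) * (self.n_type_hyper + self.n_type_hypo
                                                 + self.n_tissue_hyper + self.n_tissue_hypo))
        if n_planted > self.n_regions:
            raise ValueError("more planted DMRs than regions")


@dataclass
class Truth:
    """Per-region, per-class methylation levels and the planted-DMR registry."""

    regions: list[Region]
    levels: pd.DataFrame          # index: region_id; columns: class names
    registry: pd.DataFrame        # region_id, kind, direction, tissue, delta
    background_weights: dict[str, float]

    def dmr_ids(self, kind: str | None = None, direction: str | None = None,
                tissue: str | None = None) -> list[str]:
        reg = self.registry
        if kind is not None:
            reg = reg[reg["kind"] == kind]
        if direction is not None:
            reg = reg[reg["direction"] == direction]
        if tissue is not None:
            reg = reg[reg["tissue"] == tissue]
        return reg["region_id"].tolist()


@dataclass
class Cohort:
    """A fully simulated study: regions, reads, metadata, and ground truth."""

    regions: list[Region]
    reads: pd.DataFrame
    meta: pd.DataFrame
    truth: Truth
    fasta: str | None = None


def make_toy_reference(
    seed: int, n_regions: int, cpg_range: tuple[int, int] = (3, 8)
) -> tuple[str, list[Region]]:
    """A sequence whose MspI digest is exactly ``n_regions`` known regions.

    Each inter-cut interval starts CGG..., carries a drawn number of CpGs
    (ACG repeats, no accidental CCGG), and is padded with A's to a random
    length well under 350 bp. Digesting the returned sequence reproduces
    the returned region list exactly.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    lo, hi = cpg_range
    if lo < 1 or hi < lo:
        raise ValueError(f"infeasible cpg_range {cpg_range}")
    if 6 + 3 * (hi - 1) >= 340:
        raise ValueError(f"cpg_range {cpg_range} cannot fit in a <350 bp region")
    rng = np.random.default_rng(seed)
    parts = ["ATTA", "CCGG"]
    for _ in range(n_regions):
        k = int(rng.integers(lo, hi + 1))
        pad = int(rng.integers(10, 340 - (6 + 3 * (k - 1))))
        parts.append("T" + "ACG" * (k - 1) + "A" * pad + "T")
        parts.append("CCGG")
    seq = "".join(parts)
    regions = digest_regions(seq, CHROM)
    assert len(regions) == n_regions
    return seq, regions


def write_fasta(seq: str, path: str, name: str = CHROM, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _sample_alpha_counts(m: np.ndarray, n_cpg: np.ndarray, kappa: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Methylated-CpG counts per read under the beta-binomial molecule model."""
    m = np.asarray(m, dtype=float)
    m_star = np.empty_like(m)
    interior = (m > 0.0) & (m < 1.0)
    m_star[~interior] = m[~interior]          # degenerate: fully (un)methylated class
    if interior.any():
        mi = m[interior]
        m_star[interior] = rng.beta(mi * kappa, (1.0 - mi) * kappa)
    return rng.binomial(n_cpg, m_star)


def simulate_sample(
    truth: Truth,
    source: str | tuple[str, float],
    depth: int,
    kappa: float,
    rng: np.random.Generator,
    sample_id: str,
) -> pd.DataFrame:
    """Reads for one sample: a pure class or a (tumor class, tumor fraction) plasma mixture.

    Plasma background reads are drawn from the normal-tissue blend in
    ``truth.background_weights``. Fragments span their whole region
    (digested-fragment behavior), ``depth`` reads per region.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    n_regions = len(truth.regions)
    n_reads = n_regions * depth
    region_idx = np.repeat(np.arange(n_regions), depth)
    levels = truth.levels

    if isinstance(source, tuple):
        bg_classes = [f"{t}_normal" for t in truth.background_weights]
        bg_weights = np.array(list(truth.background_weights.values()), dtype=float)
        bg_weights = bg_weights / bg_weights.sum()
        tumor_class, f = source
        if not 0.0 <= f <= 1.0:
            raise ValueError("tumor fraction must be in [0, 1]")
        is_tumor = rng.random(n_reads) < f
        bg_pick = rng.choice(len(bg_classes), size=n_reads, p=bg_weights)
        level_matrix = levels[[tumor_class] + bg_classes].to_numpy()
        col = np.where(is_tumor, 0, bg_pick + 1)
        m = level_matrix[region_idx, col]
    else:
        m = levels[source].to_numpy()[region_idx]

    n_cpg = np.array([r.n_cpg for r in truth.regions])[region_idx]
    n_meth = _sample_alpha_counts(m, n_cpg, kappa, rng)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": [truth.regions[i].chrom for i in region_idx],
            "start": [truth.regions[i].start for i in region_idx],
            "end": [truth.regions[i].end for i in region_idx],
            "n_cpg_meth": n_meth,
            "n_cpg_total": n_cpg,
        }
    )


def build_truth(config: SimConfig, seed: int) -> Truth:
    """Draw baselines and plant the DMR registry."""
    config.validate()
    rng = np.random.default_rng(seed)
    _, regions = make_toy_reference(seed, config.n_regions, config.cpg_range)
    region_ids = [r.region_id for r in regions]
    baseline = rng.uniform(0.05, 0.95, size=config.n_regions)

    classes = [f"{t}_{c}" for t in config.cancer_types for c in ("normal", "tumor")]
    levels = pd.DataFrame({c: baseline.copy() for c in classes}, index=region_ids)

    free = list(rng.permutation(config.n_regions))
    rows = []

    def plant(n: int, direction: str, kind: str, tissue: str, targets: list[str]) -> None:
        for _ in range(n):
            i = free.pop()
            rid = region_ids[i]
            if direction == "hyper":
                base = rng.uniform(0.05, min(0.25, 1.0 - config.delta - 0.05))
                shifted = base + config.delta
            else:
                base = rng.uniform(max(0.75, config.delta + 0.05), 0.95)
                shifted = base - config.delta
            levels.loc[rid, :] = base
            levels.loc[rid, targets] = shifted
            rows.append((rid, kind, direction, tissue, config.delta))

    tumor_classes = [f"{t}_tumor" for t in config.cancer_types]
    plant(config.n_shared_hyper, "hyper", "pan_cancer", "all", tumor_classes)
    plant(config.n_shared_hypo, "hypo", "pan_cancer", "all", tumor_classes)
    for t in config.cancer_types:
        plant(config.n_type_hyper, "hyper", "type", t, [f"{t}_tumor"])
        plant(config.n_type_hypo, "hypo", "type", t, [f"{t}_tumor"])
        plant(config.n_tissue_hyper, "hyper", "tissue", t, [f"{t}_normal", f"{t}_tumor"])
        plant(config.n_tissue_hypo, "hypo", "tissue", t, [f"{t}_normal", f"{t}_tumor"])

    registry = pd.DataFrame(rows, columns=["region_id", "kind", "direction", "tissue", "delta"])
    if config.background_weights:
        weights = dict(config.background_weights)
    else:
        # liver-weighted blend; normalized at sampling time
        weights = {t: (2.0 if t == "liver" else 1.0) for t in config.cancer_types}
    return Truth(regions, levels, registry, weights)


def simulate_cohort(config: SimConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full study: paired tissues, normal tissues, plasma cohorts.

    Emits, per cancer type, ``n_pairs_per_type`` tumor/adjacent-normal
    tissue pairs (tumors impure at ``tumor_purity``) and
    ``n_normals_per_tissue`` independent normal tissues; plus cancer plasma
    (``tumor_fraction`` mixtures) and noncancer plasma (pure background).
    Fully determined by ``seed``.
    """
    config = config or SimConfig()
    config.validate()
    truth = build_truth(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    depth, kappa = config.depth, config.kappa
    stages = ("I", "II", "III", "IV")

    read_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []

    def add(sample_id: str, source, material: str, tissue: str, condition: str,
            pair_id: str | None = None, stage: str | None = None) -> None:
        frame = simulate_sample(truth, source, depth, kappa, rng, sample_id)
        read_frames.append(frame)
        meta_rows.append(
            dict(sample_id=sample_id, material=material, tissue=tissue, condition=condition,
                 pair_id=pair_id, stage=stage, cohort_role="discovery" if material == "tissue" else "",
                 raw_read_count=len(frame))
        )

    for t in config.cancer_types:
        for i in range(config.n_pairs_per_type):
            pair = f"{t}_pair{i:02d}"
            add(f"{t}_tumor{i:02d}", (f"{t}_tumor", config.tumor_purity),
                "tissue", t, "tumor", pair_id=pair, stage=stages[i % 4])
            add(f"{t}_adj{i:02d}", f"{t}_normal", "tissue", t, "adjacent_normal", pair_id=pair)
        for i in range(config.n_normals_per_tissue):
            add(f"{t}_norm{i:02d}", f"{t}_normal", "tissue", t, "normal")
        for i in range(config.n_cancer_plasma_per_type):
            add(f"{t}_plasma{i:02d}", (f"{t}_tumor", config.tumor_fraction),
                "plasma", t, "cancer", stage=stages[i % 4])
    for i in range(config.n_noncancer_plasma):
        add(f"nc_plasma{i:02d}", (truth.levels.columns[0], 0.0), "plasma", "", "noncancer")

    reads = pd.concat(read_frames, ignore_index=True)[READ_COLUMNS]
    meta = pd.DataFrame(meta_rows)[META_COLUMNS]
    fasta, _ = make_toy_reference(seed, config.n_regions, config.cpg_range)
    return Cohort(truth.regions, reads, meta, truth, fasta)
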