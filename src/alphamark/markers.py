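"""Read-level discovery of differential methylation markers.

A marker is a unit region where, at some alpha-value threshold, one sample
group carries significantly more directional reads (hypermethylated reads
with alpha >= alpha_hyper, or hypomethylated reads with alpha <= alpha_hypo)
than the other. The threshold is learned per region by grid search: for each
candidate threshold, every tumor/normal pair is scored with a one-sided
Fisher exact test on directional vs non-directional read counts, and the
threshold maximizing the number of significant pairs wins. The number of
supporting pairs measures marker stability; candidates must also clear a
reference panel of noncancer plasma samples (cancer-specific markers only)
so that markers silent in healthy cfDNA background are preferred.

Four marker panels feed the downstream classifier: cancer-specific hyper and
hypo (tumor vs adjacent normal, or tumor-type vs tumor-type for
tissue-of-origin), and tissue-specific hyper and hypo (normal tissue vs
normal tissue).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .read_io import AlphaDistribution

HYPER = "hyper"
HYPO = "hypo"

DEFAULT_GRID = np.round(np.linspace(0.0, 1.0, 21), 2)


@dataclass
class DiscoveryParams:
    """Knobs of the marker discovery procedure.

    grid          : candidate alpha thresholds searched per region
    p_cut         : per-pair one-sided Fisher significance cut
    support_frac  : minimum fraction of pairs that must be significant
    max_frac      : reference plasma sample "clean" ceiling on directional read fraction
    min_pass_frac : minimum fraction of clean reference samples
    top_m         : markers kept per contrast before merging
    n_pseudo_pairings : seeded random matchings for unpaired contrasts
    fdr_q         : optional Benjamini-Hochberg cut on pooled per-region p-values
    """

    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    p_cut: float = 0.05
    support_frac: float = 2.0 / 3.0
    max_frac: float = 0.05
    min_pass_frac: float = 0.9
    top_m: int = 2000
    n_pseudo_pairings: int = 5
    fdr_q: float | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["grid"] = [float(g) for g in self.grid]
        return d


@dataclass
class MarkerCandidate:
    region_id: str
    direction: str
    alpha_thr: float
    n_support: float
    mean_delta: float
    pass_reference: bool = True


@dataclass
class MarkerSet:
    """Ranked markers for one task/direction, with discovery provenance."""

    task: str                      # detection | too | tissue
    direction: str                 # hyper | hypo
    contrast: str
    markers: list[MarkerCandidate]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def region_ids(self) -> list[str]:
        return [m.region_id for m in self.markers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.region_id, m.direction, m.alpha_thr, m.n_support, m.mean_delta, m.pass_reference)
                for m in self.markers
            ],
            columns=["region_id", "direction", "alpha_thr", "n_support", "mean_delta", "pass_reference"],
        )

    def panel_hash(self) -> str:
        payload = json.dumps(
            [(m.region_id, m.direction, round(m.alpha_thr, 6)) for m in self.markers]
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def directional_count(dist: AlphaDistribution | np.ndarray, thr: float, direction: str) -> int:
    """Number of hypermethylated (alpha >= thr) or hypomethylated (alpha <= thr) reads."""
    alphas = dist.alphas if isinstance(dist, AlphaDistribution) else np.asarray(dist)
    if direction == HYPER:
        return int(np.count_nonzero(alphas >= thr))
    if direction == HYPO:
        return int(np.count_nonzero(alphas <= thr))
    raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")


def pair_test(
    dist_a: AlphaDistribution | np.ndarray,
    dist_b: AlphaDistribution | np.ndarray,
    thr: float,
    direction: str,
) -> float:
    """One-sided Fisher exact p that group A is enriched for directional reads.

    The 2x2 table is [(directional, non-directional) in A; same in B]; the
    one-sided p is the hypergeometric upper tail at the observed A count.
    Either side empty yields the uninformative p = 1.
    """
    alphas_a = dist_a.alphas if isinstance(dist_a, AlphaDistribution) else np.asarray(dist_a)
    alphas_b = dist_b.alphas if isinstance(dist_b, AlphaDistribution) else np.asarray(dist_b)
    n_a, n_b = len(alphas_a), len(alphas_b)
    if n_a == 0 or n_b == 0:
        return 1.0
    a = directional_count(alphas_a, thr, direction)
    b = directional_count(alphas_b, thr, direction)
    return float(hypergeom.sf(a - 1, n_a + n_b, a + b, n_a))


def _grid_counts(alphas: np.ndarray, grid: np.ndarray, direction: str) -> np.ndarray:
    """Directional counts at every grid threshold, via a sorted-array scan."""
    s = np.sort(np.asarray(alphas, dtype=float))
    if direction == HYPER:
        return len(s) - np.searchsorted(s, grid, side="left")
    return np.searchsorted(s, grid, side="right")


def _support_curve(
    pair_alphas: Sequence[tuple[np.ndarray, np.ndarray]],
    direction: str,
    grid: np.ndarray,
    p_cut: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(significant-pair count, mean fraction difference) per grid threshold."""
    n_pairs, n_grid = len(pair_alphas), len(grid)
    ca = np.zeros((n_pairs, n_grid))
    cb = np.zeros((n_pairs, n_grid))
    na = np.zeros((n_pairs, 1))
    nb = np.zeros((n_pairs, 1))
    for i, (a, b) in enumerate(pair_alphas):
        na[i, 0], nb[i, 0] = len(a), len(b)
        ca[i] = _grid_counts(a, grid, direction)
        cb[i] = _grid_counts(b, grid, direction)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = hypergeom.sf(ca - 1, na + nb, ca + cb, na)
        frac_a = np.where(na > 0, ca / na, np.nan)
        frac_b = np.where(nb > 0, cb / nb, np.nan)
    p = np.where((na == 0) | (nb == 0), 1.0, p)
    support = (p < p_cut).sum(axis=0)
    delta = np.nanmean(np.where(np.isnan(frac_b), np.nan, frac_a - frac_b), axis=0)
    return support, np.nan_to_num(delta)


def select_threshold(
    pairs: Sequence[tuple[AlphaDistribution, AlphaDistribution]],
    direction: str,
    grid: np.ndarray = DEFAULT_GRID,
    p_cut: float = 0.05,
) -> tuple[float, int]:
    """Learn alpha_hyper / alpha_hypo for one region from tumor/normal pairs.

    Returns the grid threshold maximizing the number of pairs whose
    directional read counts are significantly enriched in the first member
    (one-sided Fisher p < p_cut), with ties broken toward the more extreme
    threshold (largest for hyper, smallest for hypo).
    """
    if not pairs:
        raise ValueError("select_threshold needs at least one pair")
    grid = np.asarray(grid, dtype=float)
    pair_alphas = [
        (a.alphas if isinstance(a, AlphaDistribution) else np.asarray(a),
         b.alphas if isinstance(b, AlphaDistribution) else np.asarray(b))
        for a, b in pairs
    ]
    support, _ = _support_curve(pair_alphas, direction, grid, p_cut)
    thr, n_support, _ = _pick_threshold(support, np.zeros_like(support), grid, direction)
    return thr, int(round(n_support))


def _pick_threshold(
    support: np.ndarray, delta: np.ndarray, grid: np.ndarray, direction: str
) -> tuple[float, float, float]:
    best = support.max()
    idx = np.flatnonzero(support == best)
    i = idx[-1] if direction == HYPER else idx[0]
    return float(grid[i]), float(best), float(delta[i])


def filter_by_reference(
    candidate: MarkerCandidate,
    ref_dists: Sequence[AlphaDistribution | np.ndarray],
    max_frac: float = 0.05,
    min_pass_frac: float = 0.9,
) -> bool:
    """Keep a candidate only if the reference plasma panel is clean at its threshold.

    A reference sample is clean when its directional read fraction at the
    candidate's learned threshold is <= max_frac (a sample with no reads in
    the region is trivially clean); the candidate passes when at least
    min_pass_frac of reference samples are clean.
    """
    if len(ref_dists) == 0:
        raise ValueError("reference filtration requires at least one reference plasma sample")
    n_clean = 0
    for dist in ref_dists:
        alphas = dist.alphas if isinstance(dist, AlphaDistribution) else np.asarray(dist)
        if len(alphas) == 0:
            n_clean += 1
            continue
        frac = directional_count(alphas, candidate.alpha_thr, candidate.direction) / len(alphas)
        if frac <= max_frac:
            n_clean += 1
    return n_clean / len(ref_dists) >= min_pass_frac


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    passing = np.flatnonzero(pvals[order] <= q * np.arange(1, m + 1) / m)
    mask = np.zeros(m, dtype=bool)
    if len(passing):
        mask[order[: passing[-1] + 1]] = True
    return mask


def discover_markers(
    dists: Mapping[tuple[str, str], AlphaDistribution],
    region_ids: Sequence[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
    direction: str,
    params: DiscoveryParams | None = None,
    *,
    pairing: str = "paired",
    pairs: Sequence[tuple[str, str]] | None = None,
    ref_dists_by_region: Mapping[str, Sequence[AlphaDistribution]] | None = None,
    rng: np.random.Generator | None = None,
    task: str = "detection",
    contrast: str = "",
) -> MarkerSet:
    """Discover directional markers distinguishing group A from group B.

    Paired contrasts (tumor vs its adjacent normal) use the given sample
    pairs; unpaired contrasts (tumor type vs tumor type, tissue vs tissue)
    reuse the paired machinery through seeded random pseudo-pairings whose
    per-threshold support counts are averaged over ``n_pseudo_pairings``
    matchings. Regions pass when the supporting-pair fraction reaches
    ``support_frac``; cancer-specific contrasts additionally require the
    reference plasma panel to be clean. Markers are ranked by support, then
    effect size.
    """
    params = params or DiscoveryParams()
    if len(region_ids) == 0:
        raise ValueError("empty region universe")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    if pairing == "paired":
        if pairs is None:
            raise ValueError("paired discovery requires explicit sample pairs")
        pairings = [list(pairs)]
    elif pairing == "unpaired":
        rng = rng or np.random.default_rng(0)
        n = min(len(group_a), len(group_b))
        pairings = []
        for _ in range(params.n_pseudo_pairings):
            ia = rng.permutation(len(group_a))[:n]
            ib = rng.permutation(len(group_b))[:n]
            pairings.append([(group_a[i], group_b[j]) for i, j in zip(ia, ib)])
    else:
        raise ValueError(f"pairing must be 'paired' or 'unpaired', got {pairing!r}")

    grid = np.asarray(params.grid, dtype=float)
    empty = np.empty(0)
    candidates: list[MarkerCandidate] = []
    pooled_p: list[float] = []
    n_pairs = len(pairings[0])
    for region_id in region_ids:
        support = np.zeros(len(grid))
        delta = np.zeros(len(grid))
        for matching in pairings:
            pair_alphas = [
                (_alphas_of(dists, region_id, sa, empty), _alphas_of(dists, region_id, sb, empty))
                for sa, sb in matching
            ]
            s, d = _support_curve(pair_alphas, direction, grid, params.p_cut)
            support += s
            delta += d
        support /= len(pairings)
        delta /= len(pairings)
        thr, n_support, mean_delta = _pick_threshold(support, delta, grid, direction)
        if n_support / n_pairs < params.support_frac or n_support == 0:
            continue
        cand = MarkerCandidate(region_id, direction, thr, n_support, mean_delta)
        if params.fdr_q is not None:
            a = np.concatenate([_alphas_of(dists, region_id, s, empty) for s in group_a])
            b = np.concatenate([_alphas_of(dists, region_id, s, empty) for s in group_b])
            pooled_p.append(pair_test(a, b, thr, direction))
        candidates.append(cand)

    if params.fdr_q is not None and candidates:
        keep = _bh_reject(np.asarray(pooled_p), params.fdr_q)
        candidates = [c for c, k in zip(candidates, keep) if k]

    if ref_dists_by_region is not None:
        for cand in candidates:
            cand.pass_reference = filter_by_reference(
                cand, ref_dists_by_region.get(cand.region_id, _MISSING_REF),
                params.max_frac, params.min_pass_frac,
            )
        candidates = [c for c in candidates if c.pass_reference]

    candidates.sort(key=lambda c: (-c.n_support, -c.mean_delta, c.region_id))
    candidates = candidates[: params.top_m]
    return MarkerSet(
        task=task,
        direction=direction,
        contrast=contrast,
        markers=candidates,
        provenance={"params": params.to_dict(), "pairing": pairing, "n_pairs": n_pairs},
    )


class _MissingRef(list):
    pass


_MISSING_REF = _MissingRef()


def _alphas_of(dists, region_id, sample_id, empty) -> np.ndarray:
    d = dists.get((region_id, sample_id))
    return d.alphas if d is not None else empty


def merge_marker_sets(sets: Sequence[MarkerSet], task: str, direction: str, top_m: int | None = None) -> MarkerSet:
    """Merge per-contrast marker sets, collapsing duplicate regions.

    A region discovered in several contrasts keeps its best-ranked instance
    (highest support, then largest effect), so the merged panel carries one
    threshold per region.
    """
    best: dict[str, MarkerCandidate] = {}
    for ms in sets:
        for m in ms.markers:
            cur = best.get(m.region_id)
            if cur is None or (m.n_support, m.mean_delta) > (cur.n_support, cur.mean_delta):
                best[m.region_id] = m
    merged = sorted(best.values(), key=lambda c: (-c.n_support, -c.mean_delta, c.region_id))
    if top_m is not None:
        merged = merged[:top_m]
    return MarkerSet(
        task=task,
        direction=direction,
        contrast="merged(" + "; ".join(ms.contrast for ms in sets) + ")",
        markers=merged,
        provenance={"n_contrasts": len(sets)},
    )


def build_marker_panels(
    dists: Mapping[tuple[str, str], AlphaDistribution],
    meta: pd.DataFrame,
    region_ids: Sequence[str],
    params: DiscoveryParams | None = None,
    seed: int = 0,
    reference_ids: Sequence[str] | None = None,
    tasks: Sequence[str] = ("detection", "too"),
) -> dict[str, dict[str, MarkerSet]]:
    """Build the four marker panels for both tasks from a discovery cohort.

    Returns ``{"detection": {...}, "too": {...}}``, each inner dict keyed by
    marker type (cancer_hyper, cancer_hypo, tissue_hyper, tissue_hypo):

    - detection cancer panels: per cancer type, paired tumor vs adjacent
      normal discovery, reference-plasma filtration, merged across types;
    - TOO cancer panels: every ordered pair of tumor types (A-enriched vs
      B-enriched are distinct markers), reference filtration, merged;
    - tissue panels (shared by both tasks): every ordered pair of normal
      tissue types, no reference filtration.
    """
    params = params or DiscoveryParams()
    rng = np.random.default_rng(seed)
    tissue_meta = meta[meta["material"] == "tissue"]

    cancer_types = sorted(tissue_meta.loc[tissue_meta["condition"] == "tumor", "tissue"].unique())
    normal_types = sorted(tissue_meta.loc[tissue_meta["condition"] == "normal", "tissue"].unique())
    if not cancer_types:
        raise ValueError("no tumor tissue samples in cohort")
    if len(normal_types) < 2:
        raise ValueError("tissue-specific discovery needs >=2 normal tissue types")

    if reference_ids is None:
        reference_ids = meta.loc[meta["cohort_role"] == "reference_plasma", "sample_id"].tolist()
    ref_by_region = {
        rid: [dists[(rid, s)] for s in reference_ids if (rid, s) in dists]
        for rid in region_ids
    }
    if any(len(v) == 0 for v in ref_by_region.values()):
        # a region no reference sample covers: treat as clean panel of the covered samples;
        # an entirely uncovered region falls back to the full (empty-read) panel
        empty_panel = [AlphaDistribution("", s, np.empty(0)) for s in reference_ids]
        ref_by_region = {
            rid: (v if v else empty_panel) for rid, v in ref_by_region.items()
        }

    def _ids(mask) -> list[str]:
        return tissue_meta.loc[mask, "sample_id"].tolist()

    # --- detection: paired tumor vs adjacent normal per cancer type ---
    det_sets: dict[str, list[MarkerSet]] = {HYPER: [], HYPO: []}
    for ct in cancer_types if "detection" in tasks else []:
        tumors = tissue_meta[(tissue_meta["tissue"] == ct) & (tissue_meta["condition"] == "tumor")]
        normals = tissue_meta[
            (tissue_meta["tissue"] == ct) & (tissue_meta["condition"] == "adjacent_normal")
        ]
        if tumors.empty or normals.empty:
            raise ValueError(f"cancer type {ct!r} lacks tumor/adjacent-normal tissue samples")
        by_pair = dict(zip(normals["pair_id"], normals["sample_id"]))
        sample_pairs = [
            (t.sample_id, by_pair[t.pair_id])
            for t in tumors.itertuples()
            if t.pair_id in by_pair
        ]
        for direction in (HYPER, HYPO):
            det_sets[direction].append(
                discover_markers(
                    dists, region_ids, tumors["sample_id"].tolist(), normals["sample_id"].tolist(),
                    direction, params, pairing="paired", pairs=sample_pairs,
                    ref_dists_by_region=ref_by_region, task="detection",
                    contrast=f"{ct}-tumor-vs-adjacent",
                )
            )

    # --- TOO: ordered pairwise tumor-type contrasts, pseudo-paired ---
    too_sets: dict[str, list[MarkerSet]] = {HYPER: [], HYPO: []}
    for ct_a in cancer_types if "too" in tasks else []:
        for ct_b in cancer_types:
            if ct_a == ct_b:
                continue
            ga = _ids((tissue_meta["tissue"] == ct_a) & (tissue_meta["condition"] == "tumor"))
            gb = _ids((tissue_meta["tissue"] == ct_b) & (tissue_meta["condition"] == "tumor"))
            for direction in (HYPER, HYPO):
                too_sets[direction].append(
                    discover_markers(
                        dists, region_ids, ga, gb, direction, params,
                        pairing="unpaired", rng=rng,
                        ref_dists_by_region=ref_by_region, task="too",
                        contrast=f"{ct_a}-vs-{ct_b}-tumor",
                    )
                )

    # --- tissue: ordered pairwise normal-tissue contrasts ---
    tissue_sets: dict[str, list[MarkerSet]] = {HYPER: [], HYPO: []}
    for t_a in normal_types:
        for t_b in normal_types:
            if t_a == t_b:
                continue
            ga = _ids((tissue_meta["tissue"] == t_a) & (tissue_meta["condition"] == "normal"))
            gb = _ids((tissue_meta["tissue"] == t_b) & (tissue_meta["condition"] == "normal"))
            if not ga:
                raise ValueError(f"normal tissue type {t_a!r} has no samples")
            for direction in (HYPER, HYPO):
                tissue_sets[direction].append(
                    discover_markers(
                        dists, region_ids, ga, gb, direction, params,
                        pairing="unpaired", rng=rng, task="tissue",
                        contrast=f"{t_a}-vs-{t_b}-normal",
                    )
                )

    tissue_hyper = merge_marker_sets(tissue_sets[HYPER], "tissue", HYPER, params.top_m)
    tissue_hypo = merge_marker_sets(tissue_sets[HYPO], "tissue", HYPO, params.top_m)
    out: dict[str, dict[str, MarkerSet]] = {}
    if "detection" in tasks:
        out["detection"] = {
            "cancer_hyper": merge_marker_sets(det_sets[HYPER], "detection", HYPER, params.top_m),
            "cancer_hypo": merge_marker_sets(det_sets[HYPO], "detection", HYPO, params.top_m),
            "tissue_hyper": tissue_hyper,
            "tissue_hypo": tissue_hypo,
        }
    if "too" in tasks:
        out["too"] = {
            "cancer_hyper": merge_marker_sets(too_sets[HYPER], "too", HYPER, params.top_m),
            "cancer_hypo": merge_marker_sets(too_sets[HYPO], "too", HYPO, params.top_m),
            "tissue_hyper": tissue_hyper,
            "tissue_hypo": tissue_hypo,
        }
    return out


def write_marker_set(ms: MarkerSet, bed_path: str, sidecar_path: str | None = None) -> None:
    """BED6+ (chrom, start, end, region_id, support score, direction) + sidecar TSV."""
    rows = []
    for m in ms.markers:
        chrom, span = m.region_id.rsplit(":", 1)
        start, end = span.split("-")
        rows.append((chrom, int(start), int(end), m.region_id, m.n_support, m.direction))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id", "score", "direction"]).to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    if sidecar_path is not None:
        df = ms.to_frame()
        df.insert(0, "contrast", ms.contrast)
        df.to_csv(sidecar_path, sep="\t", index=False)
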