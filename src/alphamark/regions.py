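"""Marker unit regions from in-silico MspI digestion.

MspI cuts C|CGG. The interval between two adjacent cut points, when shorter
than 350 bp, is the unit region at which all methylation markers are defined.
Coordinates are 0-based half-open throughout; the cut coordinate is the point
between the first C and CGG, so every region starts with ``CGG...`` and ends
``...C``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_MAX_LEN = 350
DEFAULT_MAX_N_RUN = 10

_IUPAC = frozenset("ACGTURYSWKMBDHVN")
_CCGG = re.compile(r"(?=CCGG)")


@dataclass(frozen=True, order=True)
class CutSite:
    """One MspI cut point: the coordinate between C and CGG on the plus strand."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class Region:
    """Inter-cut-site interval; the unit of all methylation markers."""

    chrom: str
    start: int
    end: int
    n_cpg: int

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


def find_cut_sites(seq: str, chrom: str) -> list[CutSite]:
    """Scan a sequence for CCGG and return cut points (motif start + 1).

    Matching is case-insensitive; IUPAC ambiguity codes are accepted in the
    sequence but never match the motif. CCGG is its own reverse complement,
    so plus-strand scanning finds every site.
    """
    if not seq:
        return []
    upper = seq.upper()
    bad = set(upper) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return [CutSite(chrom, m.start() + 1) for m in _CCGG.finditer(upper)]


def digest_regions(
    seq: str,
    chrom: str,
    cut_sites: Sequence[CutSite] | None = None,
    max_len: int = DEFAULT_MAX_LEN,
    max_n_run: int = DEFAULT_MAX_N_RUN,
) -> list[Region]:
    """Regions between consecutive cut sites, strictly shorter than ``max_len``.

    Regions spanning a run of >= ``max_n_run`` consecutive N bases are dropped
    (assembly gaps carry no usable CpG information). ``n_cpg`` counts CpG
    dinucleotides inside each interval. Fewer than two cut sites yield no
    regions.
    """
    if cut_sites is None:
        cut_sites = find_cut_sites(seq, chrom)
    upper = seq.upper()
    n_run = re.compile("N" * max_n_run) if max_n_run > 0 else None
    regions: list[Region] = []
    for a, b in zip(cut_sites, cut_sites[1:]):
        if b.pos - a.pos >= max_len:
            continue
        sub = upper[a.pos : b.pos]
        if n_run is not None and n_run.search(sub):
            continue
        regions.append(Region(chrom, a.pos, b.pos, n_cpg=sub.count("CG")))
    return regions


def digest_fasta(
    fasta_path: str,
    max_len: int = DEFAULT_MAX_LEN,
    max_n_run: int = DEFAULT_MAX_N_RUN,
) -> list[Region]:
    """Digest every sequence of a FASTA file into marker unit regions."""
    from pyfaidx import Fasta

    regions: list[Region] = []
    with Fasta(fasta_path, as_raw=True) as fasta:
        for name in fasta.keys():
            seq = str(fasta[name][:])
            regions.extend(digest_regions(seq, name, max_len=max_len, max_n_run=max_n_run))
    return regions


class RegionIndex:
    """Interval lookup over disjoint, per-chromosome sorted regions.

    Fragments are assigned to the region containing their midpoint; digested
    fragments nest inside regions, and the midpoint rule stays robust for
    WGBS-like reads that straddle a boundary.
    """

    def __init__(self, regions: Iterable[Region]):
        self.regions = list(regions)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[Region]] = {}
        for r in self.regions:
            per_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in per_chrom.items():
            rs.sort(key=lambda r: r.start)
            starts = np.array([r.start for r in rs], dtype=np.int64)
            ends = np.array([r.end for r in rs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, [r.region_id for r in rs])

    def assign(self, chrom: str, start: int, end: int) -> str | None:
        """Region id containing the fragment midpoint, or None."""
        if end <= start:
            raise ValueError(f"fragment end <= start: [{start}, {end})")
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        mid = (start + end) // 2
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        if i >= 0 and mid < ends[i]:
            return ids[i]
        return None

    def assign_many(self, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int]) -> list[str | None]:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("fragment end <= start in input")
        out: list[str | None] = [None] * len(starts)
        chrom_arr = np.asarray(chroms, dtype=object)
        mids = (starts + ends) // 2
        for chrom in pd.unique(chrom_arr):
            entry = self._by_chrom.get(chrom)
            if entry is None:
                continue
            r_starts, r_ends, ids = entry
            mask = np.flatnonzero(chrom_arr == chrom)
            idx = np.searchsorted(r_starts, mids[mask], side="right") - 1
            ok = (idx >= 0) & (mids[mask] < r_ends[np.clip(idx, 0, None)])
            for j, i, hit in zip(mask, idx, ok):
                if hit:
                    out[j] = ids[i]
        return out


def assign_region(fragment: tuple[str, int, int], index: RegionIndex) -> str | None:
    """Functional wrapper: assign one (chrom, start, end) fragment."""
    return index.assign(*fragment)


def regions_to_frame(regions: Iterable[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.region_id, r.length, r.n_cpg) for r in regions],
        columns=["chrom", "start", "end", "region_id", "length", "n_cpg"],
    )


def write_bed(regions: Iterable[Region], bed_path: str, sidecar_path: str | None = None) -> None:
    """BED4 (chrom, start, end, region_id) plus optional TSV with length and n_cpg."""
    df = regions_to_frame(regions)
    df[["chrom", "start", "end", "region_id"]].to_csv(bed_path, sep="\t", header=False, index=False)
    if sidecar_path is not None:
        df[["region_id", "length", "n_cpg"]].to_csv(sidecar_path, sep="\t", index=False)


def read_bed(bed_path: str, sidecar_path: str | None = None) -> list[Region]:
    df = pd.read_csv(bed_path, sep="\t", header=None, names=["chrom", "start", "end", "region_id"])
    n_cpg = {}
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t")
        n_cpg = dict(zip(side["region_id"], side["n_cpg"]))
    return [
        Region(row.chrom, int(row.start), int(row.end), int(n_cpg.get(row.region_id, 0)))
        for row in df.itertuples()
    ]
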