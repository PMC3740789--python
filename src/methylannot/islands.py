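"""Genome-wide CpG density classification.

Two classification systems are produced from the same scanner:

* density classes HC (CG content >55%, Obs/Exp CpG >0.75, length >500 bp)
  and IC (CG >50%, Obs/Exp >0.48, length >200 bp), merged into the four
  probe classes HC / IC / ICshore / LC, and
* UCSC-style islands (CG >50%, Obs/Exp >0.60, length >200 bp) with the
  derived shore (2 kb flanks), shelf (next 2 kb) and sea probe classes.

All thresholds are strict inequalities.  Windows containing N never
qualify, so assembly gaps break islands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval

EN_DASH = "–"


@dataclass(frozen=True)
class IslandParams:
    min_gc: float
    min_oe: float
    min_len: int


HC_PARAMS = IslandParams(min_gc=0.55, min_oe=0.75, min_len=500)
IC_PARAMS = IslandParams(min_gc=0.50, min_oe=0.48, min_len=200)
UCSC_PARAMS = IslandParams(min_gc=0.50, min_oe=0.60, min_len=200)


@dataclass(frozen=True)
class CpgIsland:
    interval: GenomicInterval
    density_class: str  # "HC", "IC", "ICshore" or "UCSC"
    name: str


@dataclass(frozen=True)
class HilClass:
    label: str  # "HC", "IC", "ICshore" or "LC"
    island_name: str | None = None


def island_name(chrom: str, cls: str, start: int, end: int) -> str:
    """Canonical island name: 1-based inclusive coordinates, en-dash separated."""
    return f"{chrom}_{cls}:{start + 1}{EN_DASH}{end}"


def gc_content(seq: str) -> float | None:
    """Fraction of C+G among non-N bases; None if no non-N base exists."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_n = s.count("N")
    denom = len(s) - n_n
    if denom == 0:
        return None
    return (s.count("C") + s.count("G")) / denom


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG ratio: (#CpG * length) / (#C * #G)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_c = s.count("C")
    n_g = s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return s.count("CG") * len(s) / (n_c * n_g)


class _ChromStats:
    """O(1) window statistics via prefix sums."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        is_cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        self.length = len(arr)
        self.cum_c = np.concatenate([[0], np.cumsum(is_c)])
        self.cum_g = np.concatenate([[0], np.cumsum(is_g)])
        self.cum_n = np.concatenate([[0], np.cumsum(is_n)])
        self.cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])

    def passes(self, start: int, end: int, p: IslandParams) -> bool:
        length = end - start
        if length <= p.min_len or start < 0 or end > self.length:
            return False
        if self.cum_n[end] - self.cum_n[start] > 0:
            return False
        n_c = self.cum_c[end] - self.cum_c[start]
        n_g = self.cum_g[end] - self.cum_g[start]
        if (n_c + n_g) / length <= p.min_gc:
            return False
        if n_c == 0 or n_g == 0:
            return False
        n_cpg = self.cum_cpg[end - 1] - self.cum_cpg[start]
        return n_cpg * length / (n_c * n_g) > p.min_oe

    def seed_mask(self, p: IslandParams) -> np.ndarray:
        """Boolean mask over window starts for the minimal qualifying length."""
        w = p.min_len + 1
        n = self.length - w + 1
        if n <= 0:
            return np.zeros(0, dtype=bool)
        starts = np.arange(n)
        ends = starts + w
        n_c = self.cum_c[ends] - self.cum_c[starts]
        n_g = self.cum_g[ends] - self.cum_g[starts]
        n_n = self.cum_n[ends] - self.cum_n[starts]
        n_cpg = self.cum_cpg[ends - 1] - self.cum_cpg[starts]
        gc_ok = (n_c + n_g) / w > p.min_gc
        denom = (n_c * n_g).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(denom > 0, n_cpg * w / denom, 0.0)
        return (n_n == 0) & gc_ok & (oe > p.min_oe)


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(first, last) start indices of each run of consecutive True values."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    firsts = np.concatenate([[idx[0]], idx[breaks + 1]])
    lasts = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(firsts.tolist(), lasts.tolist()))


def _scan_chromosome(seq: str, params: IslandParams) -> list[tuple[int, int]]:
    """Island intervals on one chromosome.

    Seed with every minimal-length qualifying window, fuse overlapping
    seeds, greedily extend each fused region 1 bp at a time while the
    criteria still hold, merge overlapping survivors, then trim merged
    regions that fail the criteria 1 bp at a time until they pass or die.
    """
    stats = _ChromStats(seq)
    w = params.min_len + 1
    regions = [(f, l + w) for f, l in _mask_runs(stats.seed_mask(params))]

    extended = []
    for start, end in regions:
        while start > 0 and stats.passes(start - 1, end, params):
            start -= 1
        while end < stats.length and stats.passes(start, end + 1, params):
            end += 1
        extended.append((start, end))

    merged: list[list[int]] = []
    for start, end in sorted(extended):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])

    final = []
    for start, end in merged:
        while end - start > params.min_len and not stats.passes(start, end, params):
            # trim the end whose boundary base contributes least to density
            left, right = seq[start].upper(), seq[end - 1].upper()
            if left not in "CG":
                start += 1
            elif right not in "CG":
                end -= 1
            else:
                start += 1
        if stats.passes(start, end, params):
            final.append((start, end))
    return final


def find_islands(
    genome: Mapping[str, str],
    params: IslandParams,
    density_class: str,
) -> list[CpgIsland]:
    """Scan every chromosome for islands of one density class."""
    islands = []
    for chrom in sorted(genome):
        for start, end in _scan_chromosome(genome[chrom], params):
            islands.append(
                CpgIsland(
                    interval=GenomicInterval(chrom, start, end),
                    density_class=density_class,
                    name=island_name(chrom, density_class, start, end),
                )
            )
    return islands


def _subtract(start: int, end: int, blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of [start, end) not covered by the sorted, disjoint *blocks*."""
    pieces = []
    cur = start
    for bs, be in blocks:
        if be <= cur or bs >= end:
            continue
        if bs > cur:
            pieces.append((cur, bs))
        cur = max(cur, be)
    if cur < end:
        pieces.append((cur, end))
    return pieces


def merge_hil(
    hc_islands: Sequence[CpgIsland],
    ic_islands: Sequence[CpgIsland],
    gap_tolerance: int = 0,
) -> tuple[list[CpgIsland], dict[str, list[str]]]:
    """Reconcile independently scanned HC and IC sets into HC/ICshore/IC.

    Any base of HC density stays HC.  IC-density bases outside HC regions
    become ICshore when their IC region overlaps or lies within
    ``gap_tolerance`` bp of an HC region (default: overlap or direct
    abutment), otherwise IC.  Returns the merged islands and a map from
    each ICshore island name to the adjacent HC island names.
    """
    hc_by_chrom: dict[str, list[CpgIsland]] = {}
    for isl in hc_islands:
        hc_by_chrom.setdefault(isl.interval.chrom, []).append(isl)
    for lst in hc_by_chrom.values():
        lst.sort(key=lambda i: i.interval.start)

    merged: list[CpgIsland] = list(hc_islands)
    adjacency: dict[str, list[str]] = {}
    for isl in ic_islands:
        chrom = isl.interval.chrom
        hcs = hc_by_chrom.get(chrom, [])
        neighbours = [
            h
            for h in hcs
            if isl.interval.start <= h.interval.end + gap_tolerance
            and h.interval.start <= isl.interval.end + gap_tolerance
        ]
        blocks = [(h.interval.start, h.interval.end) for h in neighbours]
        cls = "ICshore" if neighbours else "IC"
        for start, end in _subtract(isl.interval.start, isl.interval.end, blocks):
            piece = CpgIsland(
                interval=GenomicInterval(chrom, start, end),
                density_class=cls,
                name=island_name(chrom, cls, start, end),
            )
            merged.append(piece)
            if cls == "ICshore":
                adjacency[piece.name] = [h.name for h in neighbours]
    merged.sort(key=lambda i: (i.interval.chrom, i.interval.start))
    return merged, adjacency


_HIL_PRIORITY = {"HC": 0, "ICshore": 1, "IC": 2}


def classify_position_hil(
    chrom: str, pos: int, merged_islands: Iterable[CpgIsland]
) -> HilClass:
    """HIL class of a single genomic base (the target C); LC when in no island."""
    best: CpgIsland | None = None
    for isl in merged_islands:
        if isl.interval.chrom == chrom and isl.interval.contains(pos):
            if best is None or _HIL_PRIORITY[isl.density_class] < _HIL_PRIORITY[best.density_class]:
                best = isl
    if best is None:
        return HilClass("LC", None)
    return HilClass(best.density_class, best.name)


def classify_probe_hil(probe_intervals, merged_islands: Iterable[CpgIsland]) -> HilClass:
    t = probe_intervals.target_cpg
    return classify_position_hil(t.chrom, t.start, merged_islands)


def classify_position_ucsc(
    chrom: str, pos: int, islands: Iterable[CpgIsland]
) -> str:
    """UCSC-style class of a base: island / shore (<=2 kb) / shelf (<=4 kb) / sea."""
    best = None
    for isl in islands:
        if isl.interval.chrom != chrom:
            continue
        s, e = isl.interval.start, isl.interval.end
        if s <= pos < e:
            return "island"
        dist = s - pos if pos < s else pos - e + 1
        best = dist if best is None else min(best, dist)
    if best is None:
        return "sea"
    if best <= 2000:
        return "shore"
    if best <= 4000:
        return "shelf"
    return "sea"


def classify_probe_ucsc(probe_intervals, islands: Iterable[CpgIsland]) -> str:
    t = probe_intervals.target_cpg
    return classify_position_ucsc(t.chrom, t.start, islands)


def write_island_track(islands: Sequence[CpgIsland], path) -> None:
    """Write islands as BED6 with the canonical name in the name field."""
    from .io import write_bed

    write_bed(
        [i.interval for i in islands],
        path,
        names=[i.name for i in islands],
    )
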