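"""Genomic interval primitives and the two peak-overlap semantics.

All coordinates are 0-based half-open (BED convention): an interval covers
base pairs ``start .. end-1`` and its length is ``end - start``. Chromosome
names are compared by exact string match (``chr1`` != ``1``).

Two distinct notions of peak overlap are provided because condition-level
peak comparisons and region-level comparisons use different rules:

* :func:`overlap_by_summit` — peaks match when their summits lie less than
  ``max_dist`` bp apart (strict), with greedy one-to-one nearest matching.
  Used to compare the Control and LPS peak calls.
* :func:`overlap_by_bp` — an entity counts as shared when it has at least
  ``min_overlap`` bp in common with *any* entity of the other set
  (many-to-one allowed). Used for super-enhancer and TF-binding overlaps.
"""

from __future__ import annotations

import bisect
import itertools
from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "OverlapResult",
    "filter_blacklist",
    "overlap_by_summit",
    "overlap_by_bp",
    "merge_peak_sets",
    "overlap_percentage",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_width(self, other: "GenomicInterval") -> int:
        """Number of base pairs shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_width(other) >= min_overlap


@dataclass
class Peak:
    """A called peak: an interval with a summit (signal apex) and a score."""

    interval: GenomicInterval
    summit: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) for peak {self.name!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class OverlapResult:
    """Counts of shared and set-specific entities from a set comparison.

    ``pairs`` holds (a-index, b-index) matches; one-to-one under summit
    matching, possibly many-to-one under bp matching.
    """

    common: int
    only_a: int
    only_b: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def _build_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, iv in enumerate(intervals):
        trees[iv.chrom].addi(iv.start, iv.end, i)
    return trees


def filter_blacklist(peaks: list[Peak], blacklist: list[GenomicInterval]) -> list[Peak]:
    """Remove every peak sharing >= 1 bp with any blacklist region.

    Order is preserved; an empty blacklist returns the input unchanged.
    """
    if not blacklist:
        return list(peaks)
    trees = _build_trees(blacklist)
    kept = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None or not tree.overlap(p.interval.start, p.interval.end):
            kept.append(p)
    return kept


def overlap_by_summit(a: list[Peak], b: list[Peak], max_dist: int = 1000) -> OverlapResult:
    """Match peaks whose summits are less than ``max_dist`` bp apart (strict).

    Matching is greedy one-to-one: the globally closest unmatched
    same-chromosome pair is matched first, ties broken by input order, until
    no pair under the distance bound remains.
    """
    by_chrom_b: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for j, pb in enumerate(b):
        by_chrom_b[pb.chrom].append((pb.summit, j))
    for lst in by_chrom_b.values():
        lst.sort()

    candidates: list[tuple[int, int, int]] = []  # (distance, i, j)
    for i, pa in enumerate(a):
        lst = by_chrom_b.get(pa.chrom)
        if not lst:
            continue
        summits = [s for s, _ in lst]
        lo = bisect.bisect_left(summits, pa.summit - max_dist)
        hi = bisect.bisect_right(summits, pa.summit + max_dist)
        for s, j in lst[lo:hi]:
            d = abs(s - pa.summit)
            if d < max_dist:
                candidates.append((d, i, j))

    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    common = len(pairs)
    return OverlapResult(common, len(a) - common, len(b) - common, sorted(pairs))


def overlap_by_bp(
    a: list[GenomicInterval], b: list[GenomicInterval], min_overlap: int = 1
) -> OverlapResult:
    """Count entities sharing >= ``min_overlap`` bp with the other set.

    ``common`` counts entities of A matched by *any* entity of B; ``only_b``
    counts entities of B matched by no entity of A. Counts are per-entity,
    not per-pair, so many-to-one overlaps are allowed.
    """
    trees_b = _build_trees(b)
    pairs: list[tuple[int, int]] = []
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for i, iv in enumerate(a):
        tree = trees_b.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            width = min(iv.end, hit.end) - max(iv.start, hit.begin)
            if width >= min_overlap:
                pairs.append((i, hit.data))
                hit_a.add(i)
                hit_b.add(hit.data)
    return OverlapResult(len(hit_a), len(a) - len(hit_a), len(b) - len(hit_b), sorted(pairs))


def merge_peak_sets(a: list[Peak], b: list[Peak]) -> list[Peak]:
    """Union of two peak sets, fusing peaks that share >= 1 bp.

    Fused peaks span the union of their constituents; the summit, name and
    score are inherited from the highest-score constituent (ties: first in
    (chrom, start) order). Output is sorted by (chrom, start).
    """
    pool = sorted(
        itertools.chain(a, b),
        key=lambda p: (p.chrom, p.interval.start, p.interval.end),
    )
    merged: list[Peak] = []
    cur: Peak | None = None
    cur_end = 0
    best: Peak | None = None
    for p in pool:
        if cur is not None and p.chrom == cur.chrom and p.interval.start < cur_end:
            cur_end = max(cur_end, p.interval.end)
            if p.score > best.score:
                best = p
        else:
            if cur is not None:
                merged.append(_fused(cur, cur_end, best))
            cur = p
            cur_end = p.interval.end
            best = p
    if cur is not None:
        merged.append(_fused(cur, cur_end, best))
    return merged


def _fused(first: Peak, end: int, best: Peak) -> Peak:
    iv = GenomicInterval(first.chrom, first.interval.start, end)
    return Peak(interval=iv, summit=best.summit, name=best.name, score=best.score)


def overlap_percentage(common: int, total: int) -> float:
    """``100 * common / total``; errors on a zero or negative total."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= common <= total):
        raise ValueError("need 0 <= common <= total")
    return 100.0 * common / total
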