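"""Super-enhancer identification: stitch, rank, scaled tangent cutoff.

Peaks on the same chromosome separated by at most ``stitch_dist`` bp are
merged transitively into stitched enhancer regions; each region is scored by
the summed signal of its constituents and the regions are ranked by signal.
On the ranked curve, with rank scaled to x in [0, 1] and signal to
y in [0, 1], super-enhancers are the regions past the point where the
discrete slope rises above 1 and stays above 1 — the geometric "tangent of
slope 1" cutoff that separates the steep tail of exceptionally strong,
clustered enhancers from the bulk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, OverlapResult, Peak, overlap_by_bp

__all__ = [
    "StitchedEnhancer",
    "stitch_peaks",
    "score_stitched",
    "call_superenhancers",
    "compare_se_sets",
    "ranked_curve",
]


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituent_ids: list[str] = field(default_factory=list)
    signal: float = 0.0
    rank: int = 0  # ascending-signal rank, 1 = weakest
    is_se: bool = False


def stitch_peaks(peaks: list[Peak], stitch_dist: int = 12500) -> list[StitchedEnhancer]:
    """Merge same-chromosome peaks whose gap is <= ``stitch_dist`` bp,
    transitively; each stitched region spans min start to max end and records
    its constituent peak names."""
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end))
    out: list[StitchedEnhancer] = []
    cur: list[Peak] = []
    cur_end = 0
    for p in ordered:
        if cur and p.chrom == cur[0].chrom and p.interval.start - cur_end <= stitch_dist:
            cur.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            if cur:
                out.append(_region(cur, cur_end))
            cur = [p]
            cur_end = p.interval.end
    if cur:
        out.append(_region(cur, cur_end))
    return out


def _region(constituents: list[Peak], end: int) -> StitchedEnhancer:
    iv = GenomicInterval(constituents[0].chrom, constituents[0].interval.start, end)
    return StitchedEnhancer(iv, [p.name for p in constituents])


def score_stitched(
    stitched: list[StitchedEnhancer], signal: dict[str, float]
) -> list[StitchedEnhancer]:
    """Region signal = sum of constituent signals; ascending-signal ranks,
    ties broken by (chrom, start). Raises KeyError naming a missing peak."""
    for region in stitched:
        total = 0.0
        for pid in region.constituent_ids:
            if pid not in signal:
                raise KeyError(f"no signal value for peak {pid!r}")
            total += float(signal[pid])
        region.signal = total
    order = sorted(
        range(len(stitched)),
        key=lambda i: (stitched[i].signal, stitched[i].interval.chrom, stitched[i].interval.start),
    )
    for rank, i in enumerate(order, start=1):
        stitched[i].rank = rank
    return stitched


def se_cutoff_index(signals: np.ndarray) -> int | None:
    """Cutoff index on the ascending-sorted signal vector.

    With ranks scaled to x in [0, 1] and signals to y in [0, 1], returns the
    first index i such that every forward slope (y[j+1]-y[j])/(x[j+1]-x[j])
    for j >= i exceeds 1. Entries strictly above index i are super-enhancers.
    Returns None when no such index exists or the curve is degenerate.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        return None
    y = (s - s[0]) / (s[-1] - s[0])
    slopes = np.diff(y) * (n - 1)  # dx = 1/(n-1)
    above = slopes > 1
    # smallest i with all slopes from i on above 1
    suffix_ok = np.flip(np.cumprod(np.flip(above))).astype(bool)
    idx = np.flatnonzero(suffix_ok)
    return int(idx[0]) if idx.size else None


def call_superenhancers(stitched: list[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Fill ``is_se`` using the scaled tangent-slope-1 cutoff.

    Requires >= 3 regions; with all signals equal no super-enhancer can be
    separated and zero are called (with a warning).
    """
    if len(stitched) < 3:
        raise ValueError("need at least 3 stitched regions to call super-enhancers")
    signals = np.array([r.signal for r in stitched], dtype=float)
    for r in stitched:
        r.is_se = False
    if signals.max() == signals.min():
        warnings.warn("all region signals equal: no super-enhancers called", stacklevel=2)
        return stitched
    cut = se_cutoff_index(signals)
    if cut is None:
        warnings.warn("no tangent cutoff found: no super-enhancers called", stacklevel=2)
        return stitched
    order = sorted(
        range(len(stitched)),
        key=lambda i: (stitched[i].signal, stitched[i].interval.chrom, stitched[i].interval.start),
    )
    for pos, i in enumerate(order):
        stitched[i].is_se = pos > cut
    return stitched


def compare_se_sets(a: list[StitchedEnhancer], b: list[StitchedEnhancer]) -> OverlapResult:
    """Overlap (>= 1 bp in common) between the super-enhancers of two sets."""
    iv_a = [r.interval for r in a if r.is_se]
    iv_b = [r.interval for r in b if r.is_se]
    return overlap_by_bp(iv_a, iv_b, min_overlap=1)


def ranked_curve(stitched: list[StitchedEnhancer]) -> np.ndarray:
    """(rank, signal) pairs sorted by ascending rank, for plotting/export."""
    ordered = sorted(stitched, key=lambda r: r.rank)
    return np.array([[r.rank, r.signal] for r in ordered], dtype=float)
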