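"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity from first principles (per-bp sets, full
enumeration, exhaustive scans) without sharing code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bp_overlap_width(a_chrom, a_start, a_end, b_chrom, b_start, b_end) -> int:
    """Overlap width as the size of the intersection of the per-bp sets."""
    if a_chrom != b_chrom:
        return 0
    return len(set(range(a_start, a_end)) & set(range(b_start, b_end)))


def se_cutoff_bruteforce(signals) -> set[int]:
    """Indices (into the ascending sort) called super-enhancer by an explicit
    scan: smallest i such that every scaled forward slope after i exceeds 1,
    entries strictly above i qualify."""
    s = sorted(float(v) for v in signals)
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        return set()
    x = [i / (n - 1) for i in range(n)]
    y = [(v - s[0]) / (s[-1] - s[0]) for v in s]
    slopes = [(y[i + 1] - y[i]) / (x[i + 1] - x[i]) for i in range(n - 1)]
    for i in range(n - 1):
        if all(sl > 1 for sl in slopes[i:]):
            return set(range(i + 1, n))
    return set()


def wilcoxon_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating every assignment of the
    pooled ranks to the first sample (ties not supported)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    w_obs = sum(ranks[v] for v in a)
    mean = n1 * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean)
    count = total = 0
    for comb in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(comb) - mean) >= dev - 1e-12:
            count += 1
    return count / total


def chi2_observed_expected(a, b, c, d) -> float:
    """Generic sum over cells of (observed - expected)^2 / expected."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


def pearson_perm_p(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = abs(np.corrcoef(x, rng.permutation(y))[0, 1])
        if r >= r_obs - 1e-12:
            hits += 1
    return hits / n_perm


def classify_summit_bruteforce(pos, chrom, genes, promoter_flank=2000, tts_flank=1000) -> str:
    """Feature of a summit position by explicit membership checks against
    per-bp coordinate sets, honouring the annotation precedence."""
    same = [g for g in genes if g.chrom == chrom]
    if any(g.tss - promoter_flank <= pos <= g.tss + promoter_flank for g in same):
        return "Promoter"
    if any(any(iv.start <= pos < iv.end for iv in g.utr5) for g in same):
        return "5UTR"
    if any(any(iv.start <= pos < iv.end for iv in g.exons) for g in same):
        return "Exon"
    for g in same:
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        if pos in set(range(lo, hi + 1)):
            return "Intron"
    if any(any(iv.start <= pos < iv.end for iv in g.utr3) for g in same):
        return "3UTR"
    if any(g.tes - tts_flank <= pos <= g.tes + tts_flank for g in same):
        return "TTS"
    return "Intergenic"


def closest_gene_bruteforce(peak, genes, max_dist=1_000_000):
    """Exhaustive all-gene scan for the closest-TSS assignment."""
    best = None
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom != peak.chrom:
            continue
        s, e = peak.interval.start, peak.interval.end
        d = 0 if s <= g.tss < e else min(abs(g.tss - s), abs(g.tss - (e - 1)))
        if best is None or d < best[0]:
            best = (d, g.gene_id)
    if best is None or best[0] > max_dist:
        return None, None
    return best[1], best[0]


def fisher_z_interval(r: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation estimate."""
    zr = math.atanh(r)
    half = z / math.sqrt(n - 3)
    return math.tanh(zr - half), math.tanh(zr + half)
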