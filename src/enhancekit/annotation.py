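"""Peak-to-feature annotation and the enhancer/promoter dichotomy.

Each peak is classified by its summit position into exactly one genomic
feature class, with precedence Promoter > 5UTR > Exon > Intron > 3UTR > TTS >
Intergenic (features overlap, so an order is required; this mirrors the
conventional annotation hierarchy). The promoter window is +/- 2 kb around
any TSS; the TTS window is +/- 1 kb around any transcription end.

The dichotomy collapses features into the regulatory classes used when
contrasting enhancers with promoters: enhancer-like (Intergenic, Intron,
3UTR, TTS), promoter-like (Promoter, 5UTR) and other (Exon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval, Peak

__all__ = [
    "GeneModel",
    "PeakAnnotation",
    "FEATURES",
    "classify_feature",
    "distance_to_tss",
    "dichotomize",
    "annotate_peaks",
]

FEATURES = ("Promoter", "5UTR", "Exon", "Intron", "3UTR", "TTS", "Intergenic")

_DICHOTOMY = {
    "Promoter": "promoter-like",
    "5UTR": "promoter-like",
    "Exon": "other",
    "Intron": "enhancer-like",
    "3UTR": "enhancer-like",
    "TTS": "enhancer-like",
    "Intergenic": "enhancer-like",
}


@dataclass
class GeneModel:
    """A gene: strand-aware TSS/TES plus exon (and optional UTR) structure."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        span = self.span
        for ex in self.exons:
            if ex.start < span.start or ex.end > span.end:
                raise ValueError(f"exon {ex} outside gene span of {self.gene_id}")

    @classmethod
    def from_span(cls, gene_id: str, chrom: str, strand: str, start: int, end: int,
                  exons=None, utr5=None, utr3=None) -> "GeneModel":
        """Build from a half-open genomic span; the TSS is the 5' end
        (``start`` on '+', ``end - 1`` on '-') and the TES the 3' end."""
        if end <= start:
            raise ValueError(f"gene {gene_id}: end must be > start")
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        return cls(gene_id, chrom, strand, tss, tes,
                   exons=list(exons or []), utr5=list(utr5 or []), utr3=list(utr3 or []))

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1)


@dataclass
class PeakAnnotation:
    peak_id: str
    feature: str
    dist_tss: int | None  # signed bp to the closest TSS; None when undefined
    dichotomy: str = ""
    gene_id: str | None = None  # gene owning the closest TSS

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if not self.dichotomy:
            self.dichotomy = _DICHOTOMY[self.feature]


def _contains(intervals: list[GenomicInterval], chrom: str, pos: int) -> bool:
    return any(iv.chrom == chrom and iv.start <= pos < iv.end for iv in intervals)


def classify_feature(
    peak: Peak,
    genes: list[GeneModel],
    promoter_flank: int = 2000,
    tts_flank: int = 1000,
) -> PeakAnnotation:
    """Assign the summit to a single feature class (see module docstring)."""
    s = peak.summit
    same = [g for g in genes if g.chrom == peak.chrom]
    feature = "Intergenic"
    if any(abs(s - g.tss) <= promoter_flank for g in same):
        feature = "Promoter"
    elif any(_contains(g.utr5, peak.chrom, s) for g in same):
        feature = "5UTR"
    elif any(_contains(g.exons, peak.chrom, s) for g in same):
        feature = "Exon"
    elif any(g.span.start <= s < g.span.end for g in same):
        feature = "Intron"
    elif any(_contains(g.utr3, peak.chrom, s) for g in same):
        feature = "3UTR"
    elif any(abs(s - g.tes) <= tts_flank for g in same):
        feature = "TTS"
    dist, gid = _nearest_tss(peak, same)
    return PeakAnnotation(peak.name, feature, dist, gene_id=gid)


def _nearest_tss(peak: Peak, same_chrom: list[GeneModel]) -> tuple[int | None, str | None]:
    best: tuple[int, str] | None = None
    best_signed = None
    for g in sorted(same_chrom, key=lambda g: g.gene_id):
        d = abs(peak.summit - g.tss)
        if best is None or d < best[0]:
            best = (d, g.gene_id)
            best_signed = peak.summit - g.tss if g.strand == "+" else g.tss - peak.summit
    if best is None:
        return None, None
    return best_signed, best[1]


def distance_to_tss(peak: Peak, genes: list[GeneModel]) -> int | None:
    """Signed distance from the summit to the nearest TSS (negative =
    upstream of the gene, accounting for strand); None when the peak's
    chromosome carries no gene. Ties go to the lowest gene_id."""
    dist, _ = _nearest_tss(peak, [g for g in genes if g.chrom == peak.chrom])
    return dist


def dichotomize(a: PeakAnnotation) -> PeakAnnotation:
    """Fill the enhancer/promoter dichotomy from the feature class."""
    a.dichotomy = _DICHOTOMY[a.feature]
    return a


def annotate_peaks(peaks: list[Peak], genes: list[GeneModel],
                   promoter_flank: int = 2000, tts_flank: int = 1000) -> list[PeakAnnotation]:
    return [classify_feature(p, genes, promoter_flank, tts_flank) for p in peaks]
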