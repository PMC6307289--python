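"""Integration of H3K27ac peaks with gene expression and TF binding.

Each peak is assigned to its closest gene within 1 Mb of the peak edge (the
distance is 0 when the TSS falls inside the peak). Gene expression (FPKM and
log2FC) is attached from an RNA-seq table, the H3K27ac/expression
correlation is computed after removing noise pairs below the |log2FC|
thresholds 0.38 (H3K27ac, FC 1.3) and 0.58 (expression, FC 1.5), and TF
(e.g. RELA) binding is quantified at peaks from a fragment interval set,
scaled to a 10-million-fragment library.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .annotation import GeneModel
from .intervals import GenomicInterval, Peak, _build_trees
from .stats import pearson_test, wilcoxon_rank_sum

__all__ = [
    "ExpressionRecord",
    "PeakGeneLink",
    "assign_closest_gene",
    "attach_expression",
    "correlate_h3k27ac_expression",
    "quantify_signal_at_peaks",
    "bin_and_average",
    "compare_groups_signal",
]

SIGNAL_SCALE = 10_000_000  # fragments-per-10M normalization


@dataclass
class ExpressionRecord:
    gene_id: str
    fpkm_control: float
    fpkm_lps: float
    log2fc: float

    def __post_init__(self) -> None:
        if self.fpkm_control < 0 or self.fpkm_lps < 0:
            raise ValueError("FPKM must be >= 0")


@dataclass
class PeakGeneLink:
    peak_id: str
    gene_id: str | None
    edge_distance: int | None  # bp from peak edge to the gene TSS; 0 if inside
    expression: ExpressionRecord | None = None


def edge_distance(peak: Peak, tss: int) -> int:
    """Distance from the peak edge to a TSS: 0 when the TSS lies inside the
    (half-open) peak, else the distance to the nearest covered base."""
    start, end = peak.interval.start, peak.interval.end
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - (end - 1)))


def assign_closest_gene(
    peak: Peak, genes: list[GeneModel], max_dist: int = 1_000_000
) -> PeakGeneLink:
    """Link the peak to the closest gene TSS within ``max_dist`` of the peak
    edge; ties go to the lowest gene_id; no gene in range gives a None link."""
    best: tuple[int, str] | None = None
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom != peak.chrom:
            continue
        d = edge_distance(peak, g.tss)
        if best is None or d < best[0]:
            best = (d, g.gene_id)
    if best is None or best[0] > max_dist:
        return PeakGeneLink(peak.name, None, None)
    return PeakGeneLink(peak.name, best[1], best[0])


def attach_expression(
    links: list[PeakGeneLink], expression: dict[str, ExpressionRecord]
) -> list[PeakGeneLink]:
    for link in links:
        if link.gene_id is not None:
            link.expression = expression.get(link.gene_id)
    return links


def correlate_h3k27ac_expression(
    links: list[PeakGeneLink],
    peak_log2fc: dict[str, float],
    thr_peak: float = 0.38,
    thr_expr: float = 0.58,
) -> tuple[float, float, int]:
    """Pearson correlation between peak and gene-expression log2FC.

    Noise pairs are removed first: a pair is kept only when |peak log2FC| >=
    ``thr_peak`` and |expression log2FC| >= ``thr_expr``. Returns (r, p,
    n_used); errors when fewer than 3 pairs survive.
    """
    xs, ys = [], []
    for link in links:
        if link.expression is None or link.peak_id not in peak_log2fc:
            continue
        px = float(peak_log2fc[link.peak_id])
        ey = float(link.expression.log2fc)
        if abs(px) < thr_peak or abs(ey) < thr_expr:
            continue
        xs.append(px)
        ys.append(ey)
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} pairs survive the noise filter; need >= 3")
    r, p = pearson_test(xs, ys)
    return r, p, len(xs)


def quantify_signal_at_peaks(
    peaks: list[Peak],
    fragments: list[GenomicInterval],
    libsize: int,
    scale: int = SIGNAL_SCALE,
) -> np.ndarray:
    """Per-peak fragment counts (>= 1 bp overlap) scaled to ``scale``
    fragments of library; half-open coordinates throughout."""
    if libsize <= 0:
        raise ValueError("libsize must be > 0")
    trees = _build_trees(fragments)
    counts = np.zeros(len(peaks), dtype=float)
    for i, p in enumerate(peaks):
        tree = trees.get(p.chrom)
        if tree is not None:
            counts[i] = len(tree.overlap(p.interval.start, p.interval.end))
    return counts * (scale / libsize)


def bin_and_average(values, bin: int = 25) -> np.ndarray:
    """Means of consecutive bins of ``bin`` values, in the given order; the
    final partial bin is averaged over its actual size."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if bin <= 0:
        raise ValueError("bin must be positive")
    return np.array(
        [values[i : i + bin].mean() for i in range(0, values.size, bin)], dtype=float
    )


def compare_groups_signal(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two signal distributions."""
    return wilcoxon_rank_sum(a, b)


def links_by_gene(links: list[PeakGeneLink]) -> dict[str, list[PeakGeneLink]]:
    by_gene: dict[str, list[PeakGeneLink]] = defaultdict(list)
    for link in links:
        if link.gene_id is not None:
            by_gene[link.gene_id].append(link)
    return by_gene
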