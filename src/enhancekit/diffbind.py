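"""Differential-binding analysis of two-condition ChIP-seq tag counts.

The procedure operates on a peaks x samples count matrix for a
Control/treatment (LPS) design with replicates:

1. depth scaling to the median library size, then decile-stratified GC
   correction (:func:`normalize_counts`);
2. per-peak fold over the row median (:func:`fold_over_row_median`);
3. selection of differential peaks whose condition fold change exceeds a
   threshold, 1.5 by default (:func:`select_variable_peaks`);
4. k-means clustering of the selected fold vectors into k=4 groups
   (:func:`cluster_groups`), relabelled so cluster 1 has the highest mean
   treatment fold;
5. Group-1 labelling — the treatment-increased peaks, i.e. members of a
   cluster whose centroid is high in both treatment replicates and low in
   both control replicates, that are individually higher in every treatment
   replicate than in every control replicate (:func:`label_group1`).

Note on step 3: with a 2x2 design the fold over the row median saturates at
2*FC/(1+FC) < 2, so a literal "any fold > 1.5" cut would only admit peaks
with a >3-fold condition change and would exclude typical ~2-fold activation
events; selection therefore thresholds the (pseudocounted) condition fold
change itself. docs/methods.md discusses the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import Peak

__all__ = [
    "CountMatrix",
    "DiffBindResult",
    "RankedSets",
    "normalize_counts",
    "fold_over_row_median",
    "select_variable_peaks",
    "cluster_groups",
    "label_group1",
    "compute_log2fc",
    "rank_extract",
]

CONTROL = "Control"
TREATMENT = "LPS"


@dataclass
class CountMatrix:
    """Peaks x samples tag counts with per-peak GC content.

    ``samples`` is an ordered DataFrame with columns ``sample``,
    ``condition`` (Control / LPS), ``replicate`` and ``libsize``. The design
    may have any number of replicates; the study design is 2 conditions x 2
    replicates.
    """

    peaks: list[Peak]
    samples: pd.DataFrame
    counts: np.ndarray
    gc: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        n, s = self.counts.shape
        if n != len(self.peaks):
            raise ValueError("counts rows must match number of peaks")
        if s != len(self.samples):
            raise ValueError("counts columns must match number of samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")
        for col in ("sample", "condition", "replicate", "libsize"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")

    @property
    def libsizes(self) -> np.ndarray:
        return self.samples["libsize"].to_numpy(dtype=float)

    def condition_columns(self, condition: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["condition"] == condition).to_numpy())
        if idx.size == 0:
            raise ValueError(f"no samples with condition {condition!r}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "peak_id": [p.name for p in self.peaks],
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
                "summit": [p.summit for p in self.peaks],
                "gc": self.gc,
            }
        )
        for j, name in enumerate(self.samples["sample"]):
            df[name] = self.counts[:, j]
        return df


@dataclass
class DiffBindResult:
    """Accumulating result of the differential-binding stages."""

    matrix: CountMatrix
    folds: np.ndarray
    degenerate: np.ndarray  # rows with zero median: folds set to 0
    log2fc: np.ndarray | None = None
    selected: np.ndarray | None = None  # boolean mask over peaks
    cluster: np.ndarray | None = None  # 1..k for clustered peaks, 0 = unchanged
    centroids: np.ndarray | None = None  # k x samples, ordered by cluster id
    group1: np.ndarray | None = None
    group1_clusters: list[int] = field(default_factory=list)


def normalize_counts(m: CountMatrix, n_gc_bins: int = 10) -> CountMatrix:
    """Depth scaling to the median library size, then GC-stratified correction.

    Step 1 multiplies each sample by ``median(libsizes) / libsize``. Step 2
    bins peaks into GC deciles and, within each decile, divides each sample
    by the ratio of (its decile median / pooled decile median) to (its global
    median / pooled global median) — a correction of GC-dependent relative
    trends that is exactly the identity for GC-flat data. Deciles in which
    any median is zero are skipped; with fewer than 10 peaks the GC step is
    skipped with a warning.
    """
    lib = m.libsizes
    if np.any(lib <= 0):
        raise ValueError("library sizes must be > 0")
    if m.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(m.counts.sum(axis=0) == 0):
        raise ValueError("a sample has all-zero counts")

    scaled = m.counts * (np.median(lib) / lib)[None, :]

    n = scaled.shape[0]
    if n < 10:
        warnings.warn("fewer than 10 peaks: GC correction skipped", stacklevel=2)
        return replace(m, counts=scaled, normalized=True)

    edges = np.quantile(m.gc, np.linspace(0, 1, n_gc_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # GC-flat: a single bin, identity by construction
        return replace(m, counts=scaled, normalized=True)
    bins = np.clip(np.searchsorted(edges, m.gc, side="right") - 1, 0, len(edges) - 2)

    out = scaled.copy()
    global_sample_med = np.median(scaled, axis=0)
    global_pooled_med = np.median(scaled)
    if global_pooled_med > 0:
        base = global_sample_med / global_pooled_med
        for b in range(len(edges) - 1):
            rows = bins == b
            if not rows.any():
                continue
            med_s = np.median(scaled[rows], axis=0)
            med_pooled = np.median(scaled[rows])
            if med_pooled == 0 or np.any(med_s == 0) or np.any(base == 0):
                continue  # uninformative decile
            factor = (med_s / med_pooled) / base
            out[rows] = scaled[rows] / factor[None, :]
    return replace(m, counts=out, normalized=True)


def fold_over_row_median(m: CountMatrix) -> DiffBindResult:
    """fold[i, s] = count[i, s] / median(count[i, :]).

    Rows with median zero are degenerate: their folds are set to 0 and they
    are excluded from selection downstream.
    """
    med = np.median(m.counts, axis=1)
    degenerate = med == 0
    folds = np.zeros_like(m.counts)
    ok = ~degenerate
    folds[ok] = m.counts[ok] / med[ok, None]
    return DiffBindResult(matrix=m, folds=folds, degenerate=degenerate)


def compute_log2fc(m: CountMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """log2((mean treatment + pseudocount) / (mean control + pseudocount))."""
    ctrl = m.counts[:, m.condition_columns(CONTROL)].mean(axis=1)
    trt = m.counts[:, m.condition_columns(TREATMENT)].mean(axis=1)
    return np.log2((trt + pseudocount) / (ctrl + pseudocount))


def select_variable_peaks(
    r: DiffBindResult, threshold: float = 1.5, pseudocount: float = 1.0
) -> np.ndarray:
    """Indices of differential peaks: condition fold change beyond ``threshold``.

    A peak is differential when its pseudocounted LPS/Control mean-count
    ratio exceeds ``threshold`` in either direction (strict). Degenerate rows
    are never selected. The complement is labelled unchanged.
    """
    if r.log2fc is None:
        r.log2fc = compute_log2fc(r.matrix, pseudocount)
    cut = np.log2(threshold)
    mask = (np.abs(r.log2fc) > cut) & ~r.degenerate
    r.selected = mask
    return np.flatnonzero(mask)


def cluster_groups(
    r: DiffBindResult, selected: np.ndarray, k: int = 4, seed: int = 0, n_init: int = 10
) -> DiffBindResult:
    """K-means (Euclidean, ``n_init`` restarts, fixed seed) on selected fold
    vectors; cluster ids are relabelled 1..k by descending centroid mean
    treatment fold so that cluster 1 is the most treatment-increased."""
    selected = np.asarray(selected)
    if selected.dtype == bool:
        selected = np.flatnonzero(selected)
    if len(selected) < k:
        raise ValueError(f"need at least k={k} selected peaks, got {len(selected)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(r.folds[selected])
    trt = r.matrix.condition_columns(TREATMENT)
    order = np.argsort(-km.cluster_centers_[:, trt].mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    cluster = np.zeros(len(r.folds), dtype=int)
    cluster[selected] = relabel[labels]
    r.cluster = cluster
    r.centroids = km.cluster_centers_[order]
    return r


def label_group1(r: DiffBindResult, threshold: float = 1.5) -> DiffBindResult:
    """Flag the treatment-increased peaks (Group 1).

    A cluster qualifies when its centroid has every treatment-replicate fold
    > 1, every control-replicate fold < 1 and a centroid treatment/control
    mean-fold ratio > ``threshold``. Group 1 is the union of qualifying
    clusters, restricted to peaks whose normalized counts are higher in
    every treatment replicate than in every control replicate ("increased in
    both replicates"). Emits a warning when empty.
    """
    if r.cluster is None or r.centroids is None:
        raise ValueError("cluster_groups must run before label_group1")
    m = r.matrix
    ctrl, trt = m.condition_columns(CONTROL), m.condition_columns(TREATMENT)
    qualifying = []
    for cid, ce in enumerate(r.centroids, start=1):
        ratio = ce[trt].mean() / max(ce[ctrl].mean(), 1e-12)
        if np.all(ce[trt] > 1) and np.all(ce[ctrl] < 1) and ratio > threshold:
            qualifying.append(cid)
    in_cluster = np.isin(r.cluster, qualifying)
    both_reps = m.counts[:, trt].min(axis=1) > m.counts[:, ctrl].max(axis=1)
    r.group1 = in_cluster & both_reps
    r.group1_clusters = qualifying
    if not r.group1.any():
        warnings.warn("no treatment-increased (Group 1) peaks found", stacklevel=2)
    return r


@dataclass
class RankedSets:
    """Top / middle / bottom peak index sets from the log2FC ranking."""

    top: np.ndarray
    middle: np.ndarray
    bottom: np.ndarray
    median_abs_log2fc: dict[str, float]


def rank_extract(r: DiffBindResult, n: int = 300, pseudocount: float = 1.0) -> RankedSets:
    """Rank peaks by LPS/Control ratio (descending) and extract the top,
    middle (centred on the rank median) and bottom ``n`` peaks, reporting the
    median |log2FC| of each set."""
    if r.log2fc is None:
        r.log2fc = compute_log2fc(r.matrix, pseudocount)
    N = len(r.log2fc)
    if N < 3 * n:
        raise ValueError(f"need at least 3n = {3 * n} peaks, got {N}")
    order = np.argsort(-r.log2fc, kind="stable")
    mid_start = (N - n) // 2
    sets = {
        "top": order[:n],
        "middle": order[mid_start : mid_start + n],
        "bottom": order[N - n :],
    }
    med = {k: float(np.median(np.abs(r.log2fc[v]))) for k, v in sets.items()}
    return RankedSets(sets["top"], sets["middle"], sets["bottom"], med)
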