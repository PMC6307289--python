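"""Synthetic two-condition H3K27ac datasets with known ground truth.

The generator emulates the data shapes the analysis consumes — condition
peak sets, a peaks x samples negative-binomial count matrix with GC bias and
unequal depths, a gene model, an expression table and a TF (RELA-like)
binding peak/fragment set — on a compressed genome, with every planted
effect recorded so each pipeline stage has a recoverable answer:

* a fraction of peaks is planted as LPS-increased, with log2 effect sizes
  drawn around 1.1 and applied to both LPS replicates;
* a few dense loci of strong peaks within a single stitching window act as
  super-enhancer truth;
* a TF peak co-occurs with planted peaks with high probability (0.82) and
  with background peaks rarely;
* gene expression log2FC is coupled to the planted effect of the nearest
  planted peak targeting the gene, with population correlation
  ``expr_coupling_r``.

Counts follow NB(mean, dispersion) with variance mu + dispersion * mu^2
(the edgeR convention); ``nb_dispersion = 0`` gives deterministic rounded
means. A handful of extra "artifact" peaks, disjoint from the real ones,
are emitted together with a blacklist covering them so the blacklist
filtering stage has work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .diffbind import CONTROL, TREATMENT, CountMatrix
from .integration import assign_closest_gene
from .intervals import GenomicInterval, Peak
from . import io as ekio

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_peaks_and_counts",
    "simulate_tf_binding",
    "simulate_expression",
    "simulate_all",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 400
    n_peaks: int = 5000
    frac_increased: float = 0.03
    effect_log2fc_mean: float = 1.1
    effect_log2fc_sd: float = 0.3
    nb_dispersion: float = 0.05
    gc_bias_strength: float = 0.2
    tf_prob_at_increased: float = 0.82
    tf_prob_background: float = 0.1
    expr_coupling_r: float = 0.2
    n_se_loci: int = 5
    peaks_per_se_locus: int = 8
    # secondary knobs (realism of the emitted files, not of the planted truth)
    n_artifact_peaks: int = 10
    abundance_log_mean: float = math.log(200.0)
    abundance_log_sd: float = 0.8
    expr_log2fc_sd: float = 0.8
    min_condition_count: float = 5.0
    max_gene_dist: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("frac_increased",):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("tf_prob_at_increased", "tf_prob_background"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (-1 <= self.expr_coupling_r <= 1):
            raise ValueError("expr_coupling_r must lie in [-1, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_chroms < 1 or self.chrom_length < 10_000:
            raise ValueError("need at least one chromosome of >= 10 kb")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """Planted truth: per-peak and per-gene tables aligned with the files."""

    peaks: pd.DataFrame  # peak_id, is_increased, true_log2fc, tf_bound, assigned_gene, se_locus
    genes: pd.DataFrame  # gene_id, coupling_x, log2fc
    n_se_loci: int = 0


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    artifact_peaks: list[Peak]
    blacklist: list[GenomicInterval]
    matrix: CountMatrix
    truth: GroundTruth
    condition_peaks: dict[str, list[Peak]] = field(default_factory=dict)
    tf_peaks: list[Peak] = field(default_factory=list)
    tf_fragments: list[GenomicInterval] = field(default_factory=list)
    tf_libsize: int = 0
    expression: pd.DataFrame | None = None


def _split_round_robin(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def simulate_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Place non-overlapping genes (2-6 exons, both strands) uniformly.

    Each gene gets its own slot of the chromosome so spans never overlap;
    errors when the genes cannot fit.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[0])
    chrom_sizes = {name: cfg.chrom_length for name in cfg.chrom_names()}
    genes: list[GeneModel] = []
    if cfg.n_genes == 0:
        return genes, chrom_sizes
    per_chrom = _split_round_robin(cfg.n_genes, cfg.n_chroms)
    gid = 0
    for chrom, g in zip(cfg.chrom_names(), per_chrom):
        if g == 0:
            continue
        slot = cfg.chrom_length // g
        if slot < 8000:
            raise ValueError(f"{g} genes do not fit on {chrom} ({cfg.chrom_length} bp)")
        for j in range(g):
            length = int(rng.integers(3000, min(30000, slot // 2) + 1))
            start = j * slot + int(rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 7))
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = [
                GenomicInterval(chrom, start + int(bounds[2 * e]), start + int(bounds[2 * e + 1]))
                for e in range(n_exons)
            ]
            gid += 1
            genes.append(
                GeneModel.from_span(f"g{gid:04d}", chrom, strand, start, start + length, exons=exons)
            )
    return genes, chrom_sizes


def simulate_peaks_and_counts(cfg: SimulationConfig, genes: list[GeneModel],
                              rng: np.random.Generator | None = None):
    """Peaks, NB counts, artifact peaks + blacklist, and the planted truth."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[1])
    n_total = cfg.n_peaks + cfg.n_artifact_peaks
    per_chrom = _split_round_robin(n_total, cfg.n_chroms)

    chroms: list[str] = []
    starts = np.zeros(n_total, dtype=int)
    widths = np.zeros(n_total, dtype=int)
    slot_starts = np.zeros(n_total, dtype=int)
    i = 0
    for chrom, count in zip(cfg.chrom_names(), per_chrom):
        slot = cfg.chrom_length // max(count, 1)
        if slot < 1600:
            raise ValueError(f"{count} peaks do not fit on {chrom}")
        for j in range(count):
            w = int(rng.integers(300, min(1500, slot // 2) + 1))
            starts[i] = j * slot + int(rng.integers(0, slot - w))
            widths[i] = w
            slot_starts[i] = j * slot
            chroms.append(chrom)
            i += 1

    # super-enhancer truth: dense runs of consecutive peaks on the first
    # chromosome, compressed into one 12.5 kb window each
    se_locus = np.full(n_total, -1, dtype=int)
    # artifact peaks occupy the last slots, which sit on the first chromosome
    # too when there is only one; keep the SE runs clear of them
    n0 = per_chrom[0] - (cfg.n_artifact_peaks if cfg.n_chroms == 1 else 0)
    run = cfg.peaks_per_se_locus
    if cfg.n_se_loci > 0:
        if cfg.n_se_loci * run > max(n0, 0):
            raise ValueError("super-enhancer loci do not fit on the first chromosome")
        block = n0 // cfg.n_se_loci
        for locus in range(cfg.n_se_loci):
            offset = locus * block + int(rng.integers(0, max(block - run, 1)))
            pos = slot_starts[offset]
            for t in range(run):
                idx = offset + t
                w = int(rng.integers(600, 1001))
                starts[idx] = pos
                widths[idx] = w
                se_locus[idx] = locus
                pos += w + int(rng.integers(200, 601))

    summit_off = (widths // 2) + rng.integers(-(widths // 4), widths // 4 + 1)
    peaks_all = [
        Peak(
            GenomicInterval(chroms[t], int(starts[t]), int(starts[t] + widths[t])),
            int(starts[t] + summit_off[t]),
            f"peak_{t + 1:05d}",
        )
        for t in range(n_total)
    ]
    artifact_idx = np.arange(n_total - cfg.n_artifact_peaks, n_total)
    real_idx = np.arange(n_total - cfg.n_artifact_peaks)
    artifact_peaks = [peaks_all[t] for t in artifact_idx]
    blacklist = [
        GenomicInterval(p.chrom, max(0, p.interval.start - 100), p.interval.end + 100)
        for p in artifact_peaks
    ]
    peaks = [peaks_all[t] for t in real_idx]
    se_locus = se_locus[real_idx]

    n = cfg.n_peaks
    abundance = rng.lognormal(cfg.abundance_log_mean, cfg.abundance_log_sd, n)
    boost = rng.uniform(10.0, 20.0, n)
    abundance[se_locus >= 0] *= boost[se_locus >= 0]
    gc = rng.beta(10, 10, n)

    n_inc = int(round(n * cfg.frac_increased))
    is_increased = np.zeros(n, dtype=bool)
    true_lfc = np.zeros(n)
    if n_inc:
        inc_idx = np.sort(rng.choice(n, size=n_inc, replace=False))
        is_increased[inc_idx] = True
        true_lfc[inc_idx] = rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd, n_inc)

    gc_slope = rng.normal(0.0, cfg.gc_bias_strength, 4)
    depth = rng.uniform(0.7, 1.4, 4)
    mult = np.ones((n, 4))
    mult[:, 2:] = 2.0 ** true_lfc[:, None]
    mu = abundance[:, None] * mult * np.exp(gc_slope[None, :] * (gc[:, None] - 0.5)) * depth[None, :]
    if cfg.nb_dispersion == 0:
        counts = np.rint(mu)
    else:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)

    samples = pd.DataFrame(
        {
            "sample": ["C_rep1", "C_rep2", "L_rep1", "L_rep2"],
            "condition": [CONTROL, CONTROL, TREATMENT, TREATMENT],
            "replicate": [1, 2, 1, 2],
            "libsize": counts.sum(axis=0).astype(int),
        }
    )
    matrix = CountMatrix(peaks=peaks, samples=samples, counts=counts, gc=gc)

    assigned = [
        assign_closest_gene(p, genes, cfg.max_gene_dist).gene_id or "" for p in peaks
    ]
    truth_peaks = pd.DataFrame(
        {
            "peak_id": [p.name for p in peaks],
            "is_increased": is_increased,
            "true_log2fc": true_lfc,
            "tf_bound": np.zeros(n, dtype=bool),
            "assigned_gene": assigned,
            "se_locus": se_locus,
        }
    )
    truth = GroundTruth(peaks=truth_peaks, genes=pd.DataFrame(), n_se_loci=cfg.n_se_loci)

    # reproducible per-condition peak sets: a peak is called in a condition
    # when its mean raw count there clears a floor
    condition_peaks: dict[str, list[Peak]] = {}
    for cond, cols in ((CONTROL, [0, 1]), (TREATMENT, [2, 3])):
        means = counts[:, cols].mean(axis=1)
        called = [
            Peak(p.interval, p.summit, p.name, float(means[t]))
            for t, p in enumerate(peaks)
            if means[t] >= cfg.min_condition_count
        ]
        # artifact peaks are "called" everywhere, with a mid-range score
        called += [Peak(p.interval, p.summit, p.name, 100.0) for p in artifact_peaks]
        condition_peaks[cond] = sorted(called, key=lambda p: (p.chrom, p.interval.start))

    return peaks, matrix, truth, artifact_peaks, blacklist, condition_peaks


def simulate_tf_binding(cfg: SimulationConfig, peaks: list[Peak], truth: GroundTruth,
                        rng: np.random.Generator | None = None):
    """TF peak set + fragment intervals; binding probability depends on the
    planted status of each H3K27ac peak and bound peaks get more fragments."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[2])
    inc = truth.peaks["is_increased"].to_numpy()
    prob = np.where(inc, cfg.tf_prob_at_increased, cfg.tf_prob_background)
    bound = rng.random(len(peaks)) < prob
    truth.peaks["tf_bound"] = bound

    tf_peaks: list[Peak] = []
    fragments: list[GenomicInterval] = []
    for t, p in enumerate(peaks):
        if bound[t]:
            w = int(rng.integers(150, 401))
            start = max(0, p.summit - w // 2)
            tf_peaks.append(
                Peak(GenomicInterval(p.chrom, start, start + w), p.summit, f"tf_{p.name}")
            )
        n_frag = rng.poisson(30.0 if bound[t] else 2.0)
        if n_frag:
            centers = p.summit + rng.integers(-150, 151, size=n_frag)
            for c in centers:
                s = max(0, int(c) - 100)
                fragments.append(GenomicInterval(p.chrom, s, s + 200))
    # background fragments scattered over the genome
    for chrom in cfg.chrom_names():
        pos = rng.integers(0, cfg.chrom_length - 200, size=2 * len(peaks) // cfg.n_chroms)
        fragments.extend(GenomicInterval(chrom, int(s), int(s) + 200) for s in np.sort(pos))
    return tf_peaks, fragments, len(fragments)


def simulate_expression(cfg: SimulationConfig, genes: list[GeneModel], truth: GroundTruth,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-gene FPKM and log2FC coupled to the planted peak effects.

    Each gene's coupling covariate x is the true log2FC of the nearest
    planted peak that targets it (i.e. whose closest gene within the
    assignment range is this gene); genes targeted by no planted peak have
    x = 0. The emitted log2FC is ``expr_log2fc_sd * (r * z(x) +
    sqrt(1 - r^2) * eps)`` so the population correlation with z(x) is
    exactly ``expr_coupling_r``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    if not genes:
        truth.genes = pd.DataFrame(columns=["gene_id", "coupling_x", "log2fc"])
        return pd.DataFrame(columns=["gene_id", "fpkm_control", "fpkm_lps", "log2fc"])
    tp = truth.peaks
    x = pd.Series(0.0, index=[g.gene_id for g in genes])
    planted = tp[tp["is_increased"] & (tp["assigned_gene"] != "")]
    for gene_id, sub in planted.groupby("assigned_gene"):
        if gene_id in x.index:
            # several planted peaks can target one gene; the first by peak id
            # (the nearest ones share the neighbourhood by construction) wins
            x[gene_id] = float(sub["true_log2fc"].iloc[0])
    xv = x.to_numpy()
    sd = xv.std()
    z = (xv - xv.mean()) / sd if sd > 0 else np.zeros_like(xv)
    r = cfg.expr_coupling_r
    eps = rng.standard_normal(len(genes))
    y = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eps
    log2fc = cfg.expr_log2fc_sd * y
    base = rng.lognormal(math.log(10.0), 1.2, len(genes))
    expr = pd.DataFrame(
        {
            "gene_id": x.index,
            "fpkm_control": base,
            "fpkm_lps": base * 2.0**log2fc,
            "log2fc": log2fc,
        }
    )
    truth.genes = pd.DataFrame({"gene_id": x.index, "coupling_x": xv, "log2fc": log2fc})
    return expr


def simulate_all(cfg: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage with independent seeded RNG streams."""
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(4)]
    genes, chrom_sizes = simulate_genome(cfg, streams[0])
    peaks, matrix, truth, artifacts, blacklist, condition_peaks = simulate_peaks_and_counts(
        cfg, genes, streams[1]
    )
    tf_peaks, fragments, tf_libsize = simulate_tf_binding(cfg, peaks, truth, streams[2])
    expression = simulate_expression(cfg, genes, truth, streams[3])
    return SyntheticDataset(
        config=cfg, chrom_sizes=chrom_sizes, genes=genes, peaks=peaks,
        artifact_peaks=artifacts, blacklist=blacklist, matrix=matrix, truth=truth,
        condition_peaks=condition_peaks, tf_peaks=tf_peaks, tf_fragments=fragments,
        tf_libsize=tf_libsize, expression=expression,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Emit the dataset as the plain-text files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "control_peaks": outdir / "control.narrowPeak",
        "lps_peaks": outdir / "lps.narrowPeak",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "genes": outdir / "genes.gtf",
        "expression": outdir / "expression.tsv",
        "tf_peaks": outdir / "tf_peaks.narrowPeak",
        "tf_fragments": outdir / "tf_fragments.bed",
        "blacklist": outdir / "blacklist.bed",
        "truth_peaks": outdir / "truth_peaks.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
    }
    ekio.write_peaks(paths["control_peaks"], ds.condition_peaks[CONTROL])
    ekio.write_peaks(paths["lps_peaks"], ds.condition_peaks[TREATMENT])
    ds.matrix.to_frame().to_csv(paths["counts"], sep="\t", index=False, float_format="%.6g")
    ds.matrix.samples.to_csv(paths["samples"], sep="\t", index=False)
    ekio.write_gene_models_gtf(paths["genes"], ds.genes)
    ekio.write_expression_tsv(paths["expression"], ds.expression)
    ekio.write_peaks(paths["tf_peaks"], ds.tf_peaks)
    ekio.write_fragments_bed(paths["tf_fragments"], ds.tf_fragments)
    ekio.write_bed3(paths["blacklist"], ds.blacklist)
    ds.truth.peaks.to_csv(paths["truth_peaks"], sep="\t", index=False, float_format="%.6g")
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.6g")
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in ds.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    (outdir / "tf_libsize.txt").write_text(f"{ds.tf_libsize}\n")
    paths["tf_libsize"] = outdir / "tf_libsize.txt"
    return paths
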