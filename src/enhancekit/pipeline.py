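"""End-to-end orchestration: simulate/load -> filter -> merge -> differential
binding -> super-enhancers -> annotation -> integration -> statistics.

The pipeline is driven by a :class:`PipelineConfig` (YAML-serializable; all
thresholds are config keys, nothing is hard-coded) and writes a result
directory containing a per-peak master table, per-condition super-enhancer
tables and ranked curves, overlap summaries and a statistics report. Every
summary number is recomputed from the master table, never cached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffbind as db
from . import io as ekio
from .annotation import annotate_peaks
from .diffbind import CONTROL, TREATMENT, CountMatrix
from .integration import (
    assign_closest_gene,
    bin_and_average,
    compare_groups_signal,
    correlate_h3k27ac_expression,
    quantify_signal_at_peaks,
)
from .intervals import (
    Peak,
    filter_blacklist,
    merge_peak_sets,
    overlap_by_bp,
    overlap_by_summit,
    overlap_percentage,
)
from .simulate import SimulationConfig, simulate_all, write_dataset
from .stats import ContingencyTable2x2, chi2_2x2_pearson
from .superenhancer import (
    call_superenhancers,
    ranked_curve,
    score_stitched,
    stitch_peaks,
)

logger = logging.getLogger("enhancekit")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All analysis thresholds plus either synthetic-run or file inputs."""

    seed: int = 0
    outdir: str = "results"
    # inputs: either synthetic = true (the generator supplies everything)
    # or a mapping of input file paths
    synthetic: bool = True
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    # stage thresholds
    summit_dist: int = 1000
    fold_threshold: float = 1.5
    k: int = 4
    kmeans_n_init: int = 10
    pseudocount: float = 1.0
    stitch_dist: int = 12500
    promoter_flank: int = 2000
    tts_flank: int = 1000
    max_gene_dist: int = 1_000_000
    thr_peak_log2fc: float = 0.38
    thr_expr_log2fc: float = 0.58
    bin_size: int = 25
    n_rank: int = 300

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2 for group clustering")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        for name in ("summit_dist", "stitch_dist", "max_gene_dist", "bin_size", "n_rank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.synthetic:
            required = {"control_peaks", "lps_peaks", "counts", "samples", "genes",
                        "expression", "tf_peaks", "tf_fragments", "blacklist"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"missing input paths: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key!r}: {path} does not exist")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.pop("simulation", None)
    cfg = PipelineConfig(**data)
    if sim is not None:
        cfg.simulation = SimulationConfig(**sim)
    return cfg


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t")
    meta = ["peak_id", "chrom", "start", "end", "summit", "gc"]
    peaks = [
        Peak(
            interval=_iv(row), summit=int(row.summit), name=str(row.peak_id),
        )
        for row in df[meta].itertuples()
    ]
    counts = df[samples["sample"].tolist()].to_numpy(dtype=float)
    return CountMatrix(peaks=peaks, samples=samples, counts=counts, gc=df["gc"].to_numpy())


def _iv(row):
    from .intervals import GenomicInterval

    return GenomicInterval(str(row.chrom), int(row.start), int(row.end))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage in order and write the result directory.

    Returns a dict with the in-memory results and the output paths.
    """
    cfg.validate()
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "pipeline.log")
    logger.info("thresholds: %s", {
        "summit_dist": cfg.summit_dist, "fold_threshold": cfg.fold_threshold,
        "k": cfg.k, "stitch_dist": cfg.stitch_dist, "max_gene_dist": cfg.max_gene_dist,
        "thr_peak_log2fc": cfg.thr_peak_log2fc, "thr_expr_log2fc": cfg.thr_expr_log2fc,
        "bin_size": cfg.bin_size, "n_rank": cfg.n_rank, "seed": cfg.seed,
    })

    stage = "simulate"
    try:
        if cfg.synthetic:
            sim_cfg = cfg.simulation or SimulationConfig(seed=cfg.seed)
            ds = simulate_all(sim_cfg)
            paths = write_dataset(ds, outdir / "synthetic")
            inputs = {k: str(v) for k, v in paths.items()}
            tf_libsize = ds.tf_libsize
        else:
            inputs = dict(cfg.inputs)
            tf_libsize = None
            ds = None

        stage = "load"
        control = ekio.read_peaks(inputs["control_peaks"])
        lps = ekio.read_peaks(inputs["lps_peaks"])
        blacklist = ekio.read_blacklist(inputs["blacklist"])
        genes = ekio.read_gene_models_gtf(inputs["genes"])
        expr_df = ekio.read_expression_tsv(inputs["expression"])
        tf_peaks = ekio.read_peaks(inputs["tf_peaks"])
        fragments = ekio.read_fragments_bed(inputs["tf_fragments"])
        if tf_libsize is None:
            lib_file = inputs.get("tf_libsize")
            tf_libsize = int(Path(lib_file).read_text()) if lib_file else len(fragments)
        matrix = read_count_matrix(inputs["counts"], inputs["samples"])

        stage = "filter"
        control = filter_blacklist(control, blacklist)
        lps = filter_blacklist(lps, blacklist)
        logger.info("after blacklist filter: %d control, %d LPS peaks", len(control), len(lps))

        stage = "merge"
        summit_ov = overlap_by_summit(control, lps, max_dist=cfg.summit_dist)
        merged = merge_peak_sets(control, lps)
        merged_names = {p.name for p in merged}
        keep = [i for i, p in enumerate(matrix.peaks) if p.name in merged_names]
        matrix = CountMatrix(
            peaks=[matrix.peaks[i] for i in keep],
            samples=matrix.samples,
            counts=matrix.counts[keep],
            gc=matrix.gc[keep],
        )
        logger.info("merged peak set: %d regions (%d counted)", len(merged), len(keep))

        stage = "diffbind"
        norm = db.normalize_counts(matrix)
        result = db.fold_over_row_median(norm)
        result.log2fc = db.compute_log2fc(norm, cfg.pseudocount)
        selected = db.select_variable_peaks(result, cfg.fold_threshold, cfg.pseudocount)
        if len(selected) >= cfg.k:
            db.cluster_groups(result, selected, k=cfg.k, seed=cfg.seed,
                              n_init=cfg.kmeans_n_init)
            db.label_group1(result, cfg.fold_threshold)
        else:
            result.cluster = np.zeros(len(norm.peaks), dtype=int)
            result.group1 = np.zeros(len(norm.peaks), dtype=bool)
        ranked = db.rank_extract(result, n=cfg.n_rank) if len(norm.peaks) >= 3 * cfg.n_rank else None
        logger.info("differential peaks: %d selected, %d in group 1",
                    len(selected), int(result.group1.sum()))

        stage = "superenhancer"
        cond_mean = {
            CONTROL: norm.counts[:, norm.condition_columns(CONTROL)].mean(axis=1),
            TREATMENT: norm.counts[:, norm.condition_columns(TREATMENT)].mean(axis=1),
        }
        se_tables, se_sets = {}, {}
        for cond, cond_peaks in ((CONTROL, control), (TREATMENT, lps)):
            signal = {
                p.name: float(v)
                for p, v in zip(norm.peaks, cond_mean[cond])
            }
            usable = [p for p in cond_peaks if p.name in signal]
            stitched = stitch_peaks(usable, stitch_dist=cfg.stitch_dist)
            stitched = score_stitched(stitched, signal)
            stitched = call_superenhancers(stitched)
            se_sets[cond] = stitched
            se_tables[cond] = pd.DataFrame(
                {
                    "chrom": [r.interval.chrom for r in stitched],
                    "start": [r.interval.start for r in stitched],
                    "end": [r.interval.end for r in stitched],
                    "n_constituents": [len(r.constituent_ids) for r in stitched],
                    "signal": [r.signal for r in stitched],
                    "rank": [r.rank for r in stitched],
                    "is_se": [r.is_se for r in stitched],
                }
            ).sort_values(["chrom", "start"], kind="stable")
        se_overlap = overlap_by_bp(
            [r.interval for r in se_sets[CONTROL] if r.is_se],
            [r.interval for r in se_sets[TREATMENT] if r.is_se],
        )

        stage = "annotate"
        annotations = annotate_peaks(norm.peaks, genes, cfg.promoter_flank, cfg.tts_flank)

        stage = "integrate"
        links = [assign_closest_gene(p, genes, cfg.max_gene_dist) for p in norm.peaks]
        expr_map = expr_df.set_index("gene_id")
        peak_lfc = {p.name: float(result.log2fc[i]) for i, p in enumerate(norm.peaks)}
        tf_ov = overlap_by_bp([p.interval for p in norm.peaks],
                              [p.interval for p in tf_peaks])
        tf_hit = np.zeros(len(norm.peaks), dtype=bool)
        tf_hit[[i for i, _ in tf_ov.pairs]] = True
        tf_signal = quantify_signal_at_peaks(norm.peaks, fragments, tf_libsize)

        stage = "report"
        master = _master_table(norm, result, annotations, links, expr_map, tf_hit, tf_signal)
        report = _stats_report(cfg, master, summit_ov, se_sets, se_overlap,
                               control, lps, ranked)
        _write_outputs(outdir, cfg, master, se_tables, se_sets, report)
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "master": master,
        "result": result,
        "se_sets": se_sets,
        "se_overlap": se_overlap,
        "summit_overlap": summit_ov,
        "report": report,
        "dataset": ds,
        "outdir": outdir,
    }


def _master_table(norm, result, annotations, links, expr_map, tf_hit, tf_signal):
    rows = []
    for i, p in enumerate(norm.peaks):
        ann = annotations[i]
        link = links[i]
        gene_lfc = fpkm_c = fpkm_l = np.nan
        if link.gene_id is not None and link.gene_id in expr_map.index:
            rec = expr_map.loc[link.gene_id]
            gene_lfc, fpkm_c, fpkm_l = rec["log2fc"], rec["fpkm_control"], rec["fpkm_lps"]
        rows.append(
            {
                "peak_id": p.name,
                "chrom": p.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "summit": p.summit,
                "mean_control": norm.counts[i, norm.condition_columns(CONTROL)].mean(),
                "mean_lps": norm.counts[i, norm.condition_columns(TREATMENT)].mean(),
                "log2fc": result.log2fc[i],
                "selected": bool(result.selected[i]) if result.selected is not None else False,
                "cluster": int(result.cluster[i]),
                "group1": bool(result.group1[i]),
                "feature": ann.feature,
                "dichotomy": ann.dichotomy,
                "dist_tss": ann.dist_tss if ann.dist_tss is not None else "",
                "gene_id": link.gene_id or "",
                "edge_distance": link.edge_distance if link.edge_distance is not None else "",
                "gene_log2fc": gene_lfc,
                "fpkm_control": fpkm_c,
                "fpkm_lps": fpkm_l,
                "tf_overlap": bool(tf_hit[i]),
                "tf_signal": tf_signal[i],
            }
        )
    return pd.DataFrame(rows)


def _stats_report(cfg, master, summit_ov, se_sets, se_overlap, control, lps, ranked):
    report: dict = {"thresholds": {
        "summit_dist": cfg.summit_dist, "fold_threshold": cfg.fold_threshold,
        "k": cfg.k, "stitch_dist": cfg.stitch_dist,
        "thr_peak_log2fc": cfg.thr_peak_log2fc, "thr_expr_log2fc": cfg.thr_expr_log2fc,
    }}
    total = summit_ov.common + summit_ov.only_a + summit_ov.only_b
    report["peak_overlap"] = {
        "control_peaks": len(control),
        "lps_peaks": len(lps),
        "common": summit_ov.common,
        "total": total,
        "percent_common": overlap_percentage(summit_ov.common, total) if total else 0.0,
    }
    g1 = master["group1"].to_numpy()
    report["diffbind"] = {
        "n_peaks": len(master),
        "n_selected": int(master["selected"].sum()),
        "n_group1": int(g1.sum()),
    }
    if ranked is not None:
        report["rank_extract"] = {f"median_abs_log2fc_{k}": v
                                  for k, v in ranked.median_abs_log2fc.items()}
    n_se = {c: sum(r.is_se for r in s) for c, s in se_sets.items()}
    report["superenhancers"] = {
        "n_se_control": n_se[CONTROL],
        "n_se_lps": n_se[TREATMENT],
        "common": se_overlap.common,
        "control_only": se_overlap.only_a,
        "lps_only": se_overlap.only_b,
    }
    # annotation proportions, group1 vs rest, with the chi-square on the
    # enhancer-like dichotomy
    feat = master.groupby(["group1", "feature"]).size().unstack(fill_value=0)
    report["annotation"] = {str(k): v.to_dict() for k, v in feat.iterrows()}
    enh = master["dichotomy"] == "enhancer-like"
    a = int((enh & g1).sum()); b = int((~enh & g1).sum())
    c = int((enh & ~g1).sum()); d = int((~enh & ~g1).sum())
    if min(a + b, c + d, a + c, b + d) > 0:
        chi2, p = chi2_2x2_pearson(ContingencyTable2x2(a, b, c, d))
        report["annotation_chi2"] = {"chi2": chi2, "p": p}
    # expression integration
    has_expr = master["gene_log2fc"].notna()
    if (g1 & has_expr).sum() >= 1 and (~g1 & has_expr).sum() >= 1:
        w, p = compare_groups_signal(master.loc[g1 & has_expr, "gene_log2fc"],
                                     master.loc[~g1 & has_expr, "gene_log2fc"])
        report["expression_wilcoxon"] = {"W": w, "p": p}
    links_ok = master[has_expr]
    kept = links_ok[(links_ok["log2fc"].abs() >= cfg.thr_peak_log2fc)
                    & (links_ok["gene_log2fc"].abs() >= cfg.thr_expr_log2fc)]
    if len(kept) >= 3:
        from .stats import pearson_test

        r, p = pearson_test(kept["log2fc"], kept["gene_log2fc"])
        report["expression_correlation"] = {"r": r, "p": p, "n_used": len(kept)}
    # TF integration
    t_in = int((master["tf_overlap"] & g1).sum())
    report["tf_overlap"] = {
        "group1_with_tf": t_in,
        "group1_total": int(g1.sum()),
        "percent": overlap_percentage(t_in, int(g1.sum())) if g1.sum() else 0.0,
    }
    if g1.sum() >= 1 and (~g1).sum() >= 1:
        w, p = compare_groups_signal(master.loc[g1, "tf_signal"],
                                     master.loc[~g1, "tf_signal"])
        report["tf_signal_wilcoxon"] = {"W": w, "p": p}
    # binned TF signal along the log2FC ranking
    order = master.sort_values("log2fc", ascending=False, kind="stable")
    report["tf_signal_binned"] = bin_and_average(
        order["tf_signal"].to_numpy(), bin=cfg.bin_size
    ).tolist()
    return report


def _write_outputs(outdir: Path, cfg, master, se_tables, se_sets, report) -> None:
    master.to_csv(outdir / "master_peaks.tsv", sep="\t", index=False, float_format="%.6g")
    for cond, table in se_tables.items():
        slug = cond.lower()
        table.to_csv(outdir / f"superenhancers_{slug}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        curve = ranked_curve(se_sets[cond])
        pd.DataFrame(curve, columns=["rank", "signal"]).to_csv(
            outdir / f"ranked_curve_{slug}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    cfg.to_yaml(outdir / "config_used.yaml")


def _jsonable(obj):
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _setup_logging(logfile: Path) -> None:
    for h in list(logger.handlers):
        logger.removeHandler(h)
        h.close()
    logger.setLevel(logging.INFO)
    fh = logging.FileHandler(logfile)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
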