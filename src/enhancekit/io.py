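"""Readers and writers for the plain-text formats the pipeline consumes.

Peaks travel as ENCODE narrowPeak (BED6+4) or BED6; blacklists as BED3;
gene models as GTF (gene/exon/five_prime_utr/three_prime_utr features) or as
a 6-column gene TSV plus an exon BED; counts, sample sheets and expression
tables as TSV. All genomic records are converted to 0-based half-open
coordinates on read (GTF is 1-based inclusive on disk).
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, Peak

__all__ = [
    "ParseError",
    "read_peaks",
    "write_peaks",
    "read_blacklist",
    "write_bed3",
    "write_bedgraph",
    "read_gene_models_gtf",
    "write_gene_models_gtf",
    "read_gene_models_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_fragments_bed",
    "write_fragments_bed",
]


class ParseError(ValueError):
    """A malformed line in an input file; carries the file and line number."""


def _parse_error(path, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


def read_peaks(path, format: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a narrowPeak (10-column) or BED6 file, in file order.

    For narrowPeak, column 10 is the summit offset from ``start``; a value of
    -1 (and the BED6 format, which has no summit column) falls back to the
    interval midpoint ``floor((start + end) / 2)``. The peak score is the
    narrowPeak ``signalValue`` (column 7) or the BED score for BED6.
    """
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format: {format!r}")
    ncol = 10 if format == "narrowPeak" else 6
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise _parse_error(path, lineno, f"expected {ncol} columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                if format == "narrowPeak":
                    score = float(fields[6])
                    offset = int(fields[9])
                else:
                    score = float(fields[4])
                    offset = -1
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
            if end <= start:
                raise _parse_error(path, lineno, f"end {end} <= start {start}")
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                peaks.append(Peak(GenomicInterval(chrom, start, end), summit, name, score))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return peaks


def _fmt(x: float) -> str:
    return format(x, "g")


def write_peaks(path, peaks: list[Peak], format: str = "narrowPeak") -> None:
    """Write peaks as narrowPeak (score mirrored into signalValue) or BED6."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if format == "narrowPeak":
                row = [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    p.name,
                    str(int(min(1000, max(0, round(p.score))))),
                    ".",
                    _fmt(p.score),
                    "-1",
                    "-1",
                    str(p.summit - iv.start),
                ]
            elif format == "bed6":
                row = [iv.chrom, str(iv.start), str(iv.end), p.name, _fmt(p.score), "."]
            else:
                raise ValueError(f"unknown peak format: {format!r}")
            fh.write("\t".join(row) + "\n")


def read_blacklist(path) -> list[GenomicInterval]:
    """Read a BED3(+) blacklist file."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "expected at least 3 columns")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return out


def write_bed3(path, intervals: list[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_bedgraph(path, intervals: list[GenomicInterval], values) -> None:
    """4-column UCSC bedGraph signal track."""
    if len(intervals) != len(values):
        raise ValueError("intervals and values must have equal length")
    with open(path, "w") as fh:
        for iv, v in zip(intervals, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt(float(v))}\n")


read_fragments_bed = read_blacklist
write_fragments_bed = write_bed3


# ---------------------------------------------------------------------------
# Gene models

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _gtf_attrs(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_gene_models_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF with gene/exon (and optional UTR) features."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise _parse_error(path, lineno, "expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon", "five_prime_utr", "three_prime_utr"):
                continue
            gid = _gtf_attrs(attrs).get("gene_id")
            if gid is None:
                raise _parse_error(path, lineno, "missing gene_id attribute")
            start, end = int(start1) - 1, int(end1)  # GTF is 1-based inclusive
            rec = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "span": None,
                      "exons": [], "utr5": [], "utr3": []}
            )
            iv = GenomicInterval(chrom, start, end)
            if feature == "gene":
                rec["span"] = iv
                rec["strand"] = strand
            elif feature == "exon":
                rec["exons"].append(iv)
            elif feature == "five_prime_utr":
                rec["utr5"].append(iv)
            else:
                rec["utr3"].append(iv)
    out = []
    for gid in sorted(genes):
        rec = genes[gid]
        span = rec["span"]
        if span is None:  # derive span from exons
            ex = rec["exons"]
            if not ex:
                raise ParseError(f"gene {gid} has no gene or exon feature")
            span = GenomicInterval(rec["chrom"], min(e.start for e in ex), max(e.end for e in ex))
        out.append(
            GeneModel.from_span(
                gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                start=span.start, end=span.end,
                exons=sorted(rec["exons"], key=lambda e: e.start),
                utr5=rec["utr5"], utr3=rec["utr3"],
            )
        )
    return out


def write_gene_models_gtf(path, genes: list[GeneModel], source: str = "enhancekit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def read_gene_models_tsv(gene_path, exon_bed: str | Path | None = None) -> list[GeneModel]:
    """Read a 6-column gene TSV (gene_id, chrom, strand, start, end, biotype)
    plus an optional exon BED whose name column holds the gene_id."""
    exons: dict[str, list[GenomicInterval]] = {}
    if exon_bed is not None:
        with open(exon_bed) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise _parse_error(exon_bed, lineno, "expected 4 BED columns")
                exons.setdefault(fields[3], []).append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                )
    out: list[GeneModel] = []
    with open(gene_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or fields[0].startswith("#") or fields[0] == "gene_id":
                continue
            if len(fields) < 5:
                raise _parse_error(gene_path, lineno, "expected >= 5 columns")
            gid, chrom, strand = fields[0], fields[1], fields[2]
            start, end = int(fields[3]), int(fields[4])
            ex = sorted(exons.get(gid, []), key=lambda e: e.start)
            out.append(GeneModel.from_span(gid, chrom, strand, start, end, exons=ex))
    return out


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression table: gene_id, fpkm_control, fpkm_lps, log2fc."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fpkm_control", "fpkm_lps", "log2fc"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing expression columns {sorted(missing)}")
    if (df[["fpkm_control", "fpkm_lps"]] < 0).any().any():
        raise ParseError(f"{path}: FPKM values must be >= 0")
    return df


def write_expression_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
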