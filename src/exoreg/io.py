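"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are always 0-based half-open; VCF positions and
fixed-step wiggle starts (both 1-based) are converted here and nowhere
else. Write->read round trips are lossless at the declared precision.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CloneMeasurement,
    FactorialExpressionSet,
    FormatError,
    GeneModel,
    GenomicInterval,
    ScoreTrack,
    TypedExon,
    VariantRecord,
)

PLATE_COLUMNS = ["clone_id", "batch_id", "enzyme", "well_role", "firefly", "renilla"]


# ---------------------------------------------------------------------------
# plate tables


def read_plate_table(path) -> list[CloneMeasurement]:
    """Read a CSV of dual-reporter well measurements.

    Rows that cannot yield a log-ratio (renilla <= 0, non-finite signals)
    are flagged unusable, not dropped. Vocabulary violations and missing
    columns raise :class:`FormatError` with row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out: list[CloneMeasurement] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            out.append(
                CloneMeasurement(
                    clone_id=str(row.clone_id),
                    batch_id=str(row.batch_id),
                    enzyme=str(row.enzyme),
                    well_role=str(row.well_role),
                    firefly=float(row.firefly),
                    renilla=float(row.renilla),
                )
            )
        except (FormatError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise FormatError(f"{path}: " + "; ".join(problems))
    return out


def write_plate_table(measurements, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for m in measurements:
            writer.writerow(
                [m.clone_id, m.batch_id, m.enzyme, m.well_role,
                 repr(float(m.firefly)), repr(float(m.renilla))]
            )


# ---------------------------------------------------------------------------
# BED


class BedRecord:
    """A BED3/6/12 record; ``blocks`` holds BED12 sub-intervals if present."""

    __slots__ = ("interval", "name", "score", "thick_start", "thick_end", "blocks")

    def __init__(self, interval, name=None, score=None, thick_start=None,
                 thick_end=None, blocks=None):
        self.interval = interval
        self.name = name
        self.score = score
        self.thick_start = thick_start
        self.thick_end = thick_end
        self.blocks = blocks

    def expanded(self) -> list[GenomicInterval]:
        """Block sub-intervals for BED12, else the record interval."""
        return list(self.blocks) if self.blocks else [self.interval]


def read_bed(path) -> list[BedRecord]:
    """Read BED3/BED6/BED12 (whitespace-delimited, 0-based half-open)."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            strand = f[5] if len(f) >= 6 else "."
            rec = BedRecord(
                GenomicInterval(chrom, start, end, strand),
                name=f[3] if len(f) >= 4 else None,
                score=float(f[4]) if len(f) >= 5 and f[4] != "." else None,
            )
            if len(f) >= 12:
                rec.thick_start, rec.thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(v) for v in f[10].rstrip(",").split(",")]
                starts = [int(v) for v in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise FormatError(f"{path}:{lineno}: block count mismatch")
                if starts != sorted(starts):
                    raise FormatError(f"{path}:{lineno}: blocks out of order")
                rec.blocks = [
                    GenomicInterval(chrom, start + s, start + s + sz, strand)
                    for s, sz in zip(starts, sizes)
                ]
            out.append(rec)
    return out


def write_bed(records, path) -> None:
    """Write BedRecords as BED6 (or BED3 when name/score absent)."""
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            if r.name is None and r.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "." if r.score is None else f"{r.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# gene models (BED12)


def gene_model_from_bed(rec: BedRecord, gene_id: str | None = None) -> GeneModel:
    """Build a typed GeneModel from a BED12 record.

    The thick region delimits the CDS; blocks outside it become UTRs
    (5' vs 3' resolved by strand). thickStart == thickEnd marks a
    noncoding transcript.
    """
    if rec.blocks is None:
        raise FormatError("gene models require BED12 blocks")
    strand = rec.interval.strand
    if strand not in {"+", "-"}:
        raise FormatError("gene models require an explicit strand")
    ts, te = rec.thick_start, rec.thick_end
    coding = ts is not None and te is not None and ts < te
    exons: list[TypedExon] = []
    for blk in rec.blocks:
        if not coding:
            exons.append(TypedExon(blk, "noncoding_exon"))
            continue
        pieces = []
        if blk.start < ts:
            pieces.append((blk.start, min(blk.end, ts), "left"))
        if max(blk.start, ts) < min(blk.end, te):
            pieces.append((max(blk.start, ts), min(blk.end, te), "cds"))
        if blk.end > te:
            pieces.append((max(blk.start, te), blk.end, "right"))
        for s, e, side in pieces:
            if side == "cds":
                kind = "cds"
            elif side == "left":
                kind = "utr5" if strand == "+" else "utr3"
            else:
                kind = "utr3" if strand == "+" else "utr5"
            exons.append(TypedExon(GenomicInterval(blk.chrom, s, e, strand), kind))
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(
        gene_id=gene_id or rec.name or "gene",
        chrom=rec.interval.chrom,
        strand=strand,
        exons=exons,
    )


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a BED12 file (one transcript per line)."""
    models = []
    for rec in read_bed(path):
        models.append(gene_model_from_bed(rec))
    return models


def write_gene_models(genes, path) -> None:
    """Write GeneModels as BED12. Exon segments are re-merged into blocks."""
    with open(path, "w") as fh:
        for g in genes:
            ivs = sorted(g.exonic_intervals, key=lambda iv: iv.start)
            blocks: list[list[int]] = []
            for iv in ivs:
                if blocks and blocks[-1][1] == iv.start:
                    blocks[-1][1] = iv.end
                else:
                    blocks.append([iv.start, iv.end])
            cds = sorted(g.cds_intervals(), key=lambda iv: iv.start)
            start, end = blocks[0][0], blocks[-1][1]
            ts = cds[0].start if cds else start
            te = cds[-1].end if cds else start
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - start) for s, _ in blocks)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{ts}\t{te}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# score tracks (bedGraph / fixed-step wiggle)


def read_score_track(path) -> ScoreTrack:
    """Read per-base scores from bedGraph or fixed-step wiggle.

    Wiggle 1-based starts are converted to 0-based. Overlapping records
    raise :class:`FormatError` (a base's value would be ambiguous).
    """
    track = ScoreTrack()
    mode = "bedgraph"
    chrom, pos, step, span = None, None, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(part.split("=") for part in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixedstep"
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"{path}:{lineno}: variableStep not supported")
            try:
                if mode == "fixedstep":
                    value = float(line)
                    track.add_segment(chrom, pos, [value] * span)
                    pos += step
                else:
                    f = line.split()
                    c, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                    if s < 0 or s >= e:
                        raise FormatError(f"invalid range {s}-{e}")
                    track.add_segment(c, s, np.full(e - s, v))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return track


def write_score_track(track: ScoreTrack, path, precision: int = 6) -> None:
    """Write a ScoreTrack as bedGraph, collapsing runs of equal value."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for seg_start, values in track.segments(chrom):
                run_start = 0
                for i in range(1, values.size + 1):
                    if i == values.size or values[i] != values[run_start]:
                        fh.write(
                            f"{chrom}\t{seg_start + run_start}\t{seg_start + i}\t"
                            f"{values[run_start]:.{precision}g}\n"
                        )
                        run_start = i


# ---------------------------------------------------------------------------
# variants (VCF)


def read_variants(path) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF; others are flagged, not dropped.

    MAF = min(AF, 1 - AF) from the INFO AF field when present, else from
    allele counts over non-missing genotype calls. Raises
    :class:`FormatError` when neither source exists. VCF 1-based POS is
    converted to a 0-based offset.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = len(vf.header.samples) > 0
        has_af = "AF" in vf.header.info
        for rec in vf:
            alts = rec.alts or ()
            excluded = None
            alt = alts[0] if alts else ""
            if len(alts) != 1:
                excluded = "not biallelic"
            elif len(rec.ref) != 1 or len(alt) != 1 or \
                    rec.ref.upper() not in "ACGT" or alt.upper() not in "ACGT":
                excluded = "not an SNV"
            af = rec.info.get("AF", None) if has_af else None
            if af is not None:
                af = float(af[0] if isinstance(af, tuple) else af)
            elif has_samples:
                alt_n = tot = 0
                for s in rec.samples.values():
                    for allele in s.allele_indices or ():
                        if allele is None:
                            continue
                        tot += 1
                        alt_n += int(allele > 0)
                af = alt_n / tot if tot else None
            if af is None:
                raise FormatError(
                    f"{path}: {rec.chrom}:{rec.pos} has neither AF nor genotypes"
                )
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.start,  # pysam start is already 0-based
                    ref=rec.ref.upper(),
                    alt=alt.upper() if alt else "",
                    maf=min(af, 1.0 - af),
                    excluded_reason=excluded,
                )
            )
    return out


def write_variants(records, path, contigs=None) -> None:
    """Write VariantRecords as a minimal uncompressed VCF with INFO AF.

    AF is written as the MAF (the minor allele is arbitrary here), which
    round-trips since MAF = min(AF, 1 - AF).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for c in contigs or sorted({r.chrom for r in records}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
                f"AF={r.maf:.6g}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_table(matrix_path, factors_path) -> FactorialExpressionSet:
    """Read a genes x samples TSV and a sample factor TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    # factor levels like "null" must survive as strings, not become NaN
    factors = pd.read_csv(factors_path, sep="\t", index_col=0,
                          keep_default_na=False, na_values=[""])
    factors.index = factors.index.astype(str)
    values.columns = values.columns.astype(str)
    return FactorialExpressionSet(values=values, factors=factors)


def write_expression_table(es: FactorialExpressionSet, matrix_path,
                           factors_path) -> None:
    es.values.to_csv(matrix_path, sep="\t")
    es.factors.to_csv(factors_path, sep="\t")
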