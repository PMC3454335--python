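"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open (BED convention). Formats
that use 1-based coordinates (VCF, fixed-step wiggle) are converted at the
I/O boundary and nowhere else.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}

EXON_KINDS = {"cds", "utr5", "utr3", "noncoding_exon"}

ENZYMES = {"Sau3AI", "AluI", "control"}
WELL_ROLES = {"experimental", "promoter_only", "no_promoter", "positive_enhancer"}


class FormatError(ValueError):
    """A file or record violates the expected format."""


class DataError(ValueError):
    """Input is well-formed but inconsistent with the requested analysis."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if other.chrom != self.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0


@dataclass
class CloneMeasurement:
    """One well's dual-reporter readout.

    ``usable`` is False when the well cannot yield a log-ratio (e.g.
    non-positive Renilla signal); such wells are flagged, never dropped
    silently, so downstream stages can decide what to do with them.
    """

    clone_id: str
    batch_id: str
    enzyme: str
    well_role: str
    firefly: float
    renilla: float
    usable: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise FormatError(f"unknown enzyme {self.enzyme!r}")
        if self.well_role not in WELL_ROLES:
            raise FormatError(f"unknown well role {self.well_role!r}")
        if not np.isfinite(self.renilla) or self.renilla <= 0:
            self.usable = False
            self.reason = self.reason or "renilla <= 0"
        elif not np.isfinite(self.firefly) or self.firefly <= 0:
            self.usable = False
            self.reason = self.reason or "firefly <= 0"


@dataclass(frozen=True)
class TypedExon:
    interval: GenomicInterval
    kind: str  # cds | utr5 | utr3 | noncoding_exon

    def __post_init__(self) -> None:
        if self.kind not in EXON_KINDS:
            raise FormatError(f"unknown exon kind {self.kind!r}")


@dataclass
class GeneModel:
    """Gene model as an ordered list of typed exon segments.

    ``exons`` are stored in transcript orientation (5' -> 3'): genomic
    ascending for '+' genes, descending for '-' genes. Segments never
    overlap. ``cds_frame_offset`` is the frame of the first CDS base (0-2).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[TypedExon]
    cds_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene strand must be +/- (got {self.strand!r})")
        if not 0 <= self.cds_frame_offset <= 2:
            raise FormatError("cds_frame_offset must be in 0..2")
        ivs = [e.interval for e in self.exons]
        starts = [iv.start for iv in ivs]
        expect = sorted(starts, reverse=(self.strand == "-"))
        if starts != expect:
            raise FormatError(
                f"{self.gene_id}: exons not sorted in transcript orientation"
            )
        genomic = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise FormatError(f"{self.gene_id}: overlapping exon segments")

    @property
    def exonic_intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.exons]

    @property
    def total_exonic_length(self) -> int:
        return sum(len(e.interval) for e in self.exons)

    def segments(self, kind: str) -> list[TypedExon]:
        return [e for e in self.exons if e.kind == kind]

    def kind_at(self, chrom: str, pos: int) -> str | None:
        """Exon kind at a genomic position, or None if intronic/outside."""
        for e in self.exons:
            if e.interval.contains(chrom, pos):
                return e.kind
        return None

    def cds_intervals(self) -> list[GenomicInterval]:
        """CDS segments in transcript orientation."""
        return [e.interval for e in self.exons if e.kind == "cds"]

    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_intervals())

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, 5'->3'.

        Returns None when the position is not inside a CDS segment.
        """
        off = 0
        for iv in self.cds_intervals():
            if iv.start <= pos < iv.end:
                if self.strand == "+":
                    return off + (pos - iv.start)
                return off + (iv.end - 1 - pos)
            off += len(iv)
        return None


class ScoreTrack:
    """Per-base real-valued scores over a set of genomic segments.

    Stores one float per covered base. Segments on the same chromosome may
    not overlap; querying a region with uncovered bases raises
    :class:`DataError`.
    """

    def __init__(self) -> None:
        # chrom -> parallel sorted lists of (start, values)
        self._starts: dict[str, list[int]] = {}
        self._values: dict[str, list[np.ndarray]] = {}

    def add_segment(self, chrom: str, start: int, values: Sequence[float]) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise FormatError("score segment must be a non-empty 1-D array")
        if start < 0:
            raise FormatError("score segment start must be >= 0")
        starts = self._starts.setdefault(chrom, [])
        vals = self._values.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        end = start + arr.size
        if i > 0 and starts[i - 1] + vals[i - 1].size > start:
            raise FormatError(f"overlapping score segments on {chrom} at {start}")
        if i < len(starts) and end > starts[i]:
            raise FormatError(f"overlapping score segments on {chrom} at {start}")
        # merge with adjacent segments to keep the lists short
        if i > 0 and starts[i - 1] + vals[i - 1].size == start:
            vals[i - 1] = np.concatenate([vals[i - 1], arr])
            if i < len(starts) and starts[i] == start + arr.size:
                vals[i - 1] = np.concatenate([vals[i - 1], vals[i]])
                del starts[i], vals[i]
            return
        if i < len(starts) and starts[i] == end:
            starts[i] = start
            vals[i] = np.concatenate([arr, vals[i]])
            return
        starts.insert(i, start)
        vals.insert(i, arr)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def segments(self, chrom: str) -> list[tuple[int, np.ndarray]]:
        return list(zip(self._starts.get(chrom, []), self._values.get(chrom, [])))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start, end); raises on any gap."""
        if start < 0 or start >= end:
            raise DataError("invalid query range")
        starts = self._starts.get(chrom)
        if not starts:
            raise DataError(f"no scores on {chrom}")
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            raise DataError(f"no scores at {chrom}:{start}")
        seg_start = starts[i]
        seg = self._values[chrom][i]
        if seg_start + seg.size < end:
            raise DataError(
                f"score track gap within {chrom}:{start}-{end}"
            )
        return seg[start - seg_start : end - seg_start].copy()

    def mean(self, interval: GenomicInterval) -> float:
        return float(np.mean(self.values(interval.chrom, interval.start, interval.end)))


@dataclass
class VariantRecord:
    """Biallelic SNV with minor-allele frequency (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    excluded_reason: str | None = None
    consequence: str | None = None  # synonymous | nonsynonymous | noncoding | unassigned

    @property
    def usable(self) -> bool:
        return self.excluded_reason is None


@dataclass
class FactorialExpressionSet:
    """Genes x samples expression matrix with per-sample factor labels.

    ``values``: DataFrame indexed by gene, columns = samples (log scale).
    ``factors``: DataFrame indexed by sample with column ``genotype`` and,
    for 2x2 designs, ``treatment``.
    """

    values: pd.DataFrame
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.factors.index]
        if missing:
            raise FormatError(f"samples missing from factor table: {missing}")
        if "genotype" not in self.factors.columns:
            raise FormatError("factor table must have a 'genotype' column")
        if self.factors.loc[list(self.values.columns)].isna().any().any():
            raise FormatError("incomplete factor labels")

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise DataError(f"gene {gene!r} not in expression matrix")
        return self.values.loc[gene]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (strand discarded)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    intervals: Iterable[GenomicInterval], remove: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference of genomic intervals (both sides merged first)."""
    keep = merge_intervals(intervals)
    cut = merge_intervals(remove)
    out: list[GenomicInterval] = []
    for iv in keep:
        pieces = [(iv.start, iv.end)]
        for c in cut:
            if c.chrom != iv.chrom:
                continue
            nxt = []
            for s, e in pieces:
                if c.end <= s or c.start >= e:
                    nxt.append((s, e))
                    continue
                if c.start > s:
                    nxt.append((s, c.start))
                if c.end < e:
                    nxt.append((c.end, e))
            pieces = nxt
        out.extend(GenomicInterval(iv.chrom, s, e) for s, e in pieces)
    return out
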