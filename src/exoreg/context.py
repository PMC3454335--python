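"""Genomic context of confirmed fragments.

Alignment filtering (best hit must land in an exon), exon-location
typing, feature-track overlap annotation, and CpG-island detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import DataError, GeneModel, GenomicInterval

LOCATION_LABELS = {"cds": "coding", "utr5": "5'UTR", "utr3": "3'UTR",
                   "noncoding_exon": "noncoding_exon"}


@dataclass(frozen=True)
class AlignmentRecord:
    """One genome alignment of a clone's sequence (rank 1 = best)."""

    clone_id: str
    target: GenomicInterval
    identity: float
    score: float
    rank: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise DataError("identity must be in [0, 1]")
        if self.rank < 1:
            raise DataError("rank must be >= 1")


def _exon_trees(genes) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        for e in g.exons:
            iv = e.interval
            trees.setdefault(g.chrom, IntervalTree()).addi(
                iv.start, iv.end, (g.gene_id, e.kind))
    return trees


def filter_exonic_clones(alignments, genes, min_identity: float = 0.98
                         ) -> tuple[set[str], dict[str, list[str]]]:
    """Keep clones whose best alignment lands in an exon.

    A clone is retained when its rank-1 alignment has identity >=
    ``min_identity`` and overlaps any typed exon. Clones with several
    rank-1 hits of equal score are retained (if any hit is exonic) but
    flagged ``ambiguous``. Returns (retained clone ids, flags per clone).
    """
    trees = _exon_trees(genes)
    by_clone: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_clone.setdefault(a.clone_id, []).append(a)
    retained: set[str] = set()
    flags: dict[str, list[str]] = {}
    for cid, alns in by_clone.items():
        top = [a for a in alns if a.rank == 1]
        if not top:
            flags.setdefault(cid, []).append("no rank-1 alignment")
            continue
        best_score = max(a.score for a in top)
        ties = [a for a in top if a.score == best_score]
        if len(ties) > 1:
            flags.setdefault(cid, []).append("ambiguous")
        keep = False
        for a in ties:
            if a.identity < min_identity:
                flags.setdefault(cid, []).append(
                    f"identity {a.identity:.3f} < {min_identity}")
                continue
            tree = trees.get(a.target.chrom)
            if tree is not None and tree.overlap(a.target.start, a.target.end):
                keep = True
        if keep:
            retained.add(cid)
        else:
            flags.setdefault(cid, []).append("best alignment not exonic")
    return retained, flags


def locate_element(interval: GenomicInterval, gene: GeneModel
                   ) -> tuple[str, bool]:
    """Location category of an element within its host gene.

    Returns (category, boundary_flag). The category is the exon type with
    the majority base overlap ('coding', "5'UTR", "3'UTR",
    'noncoding_exon'); spanning more than one type sets the boundary
    flag. No exonic overlap at all raises :class:`DataError` (elements in
    this pipeline are exonic by construction).
    """
    if interval.chrom != gene.chrom:
        raise DataError("element and gene are on different chromosomes")
    overlap: dict[str, int] = {}
    for e in gene.exons:
        n = interval.overlap_length(e.interval)
        if n:
            overlap[e.kind] = overlap.get(e.kind, 0) + n
    if not overlap:
        raise DataError(
            f"element {interval.chrom}:{interval.start}-{interval.end} "
            f"does not overlap exons of {gene.gene_id} (intergenic/intronic)")
    # majority rule; deterministic tie-break by fixed kind order
    order = ["cds", "utr3", "utr5", "noncoding_exon"]
    kind = max(overlap, key=lambda k: (overlap[k], -order.index(k)))
    return LOCATION_LABELS[kind], len(overlap) > 1


def annotate_overlaps(elements: dict[str, GenomicInterval],
                      tracks: dict[str, list[GenomicInterval]]) -> pd.DataFrame:
    """Any-overlap (>= 1 bp, half-open) of elements against named tracks.

    Returns a table with one row per (element, track, feature) overlap:
    columns element_id, track, feature_chrom/start/end, overlap_length.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, feats in tracks.items():
        for iv in feats:
            trees.setdefault(name, {}).setdefault(
                iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    rows = []
    for eid, iv in elements.items():
        for name in tracks:
            tree = trees.get(name, {}).get(iv.chrom)
            if tree is None:
                continue
            for hit in sorted(tree.overlap(iv.start, iv.end)):
                rows.append({
                    "element_id": eid,
                    "track": name,
                    "feature_chrom": iv.chrom,
                    "feature_start": hit.begin,
                    "feature_end": hit.end,
                    "overlap_length": min(iv.end, hit.end) - max(iv.start, hit.begin),
                })
    return pd.DataFrame(rows, columns=["element_id", "track", "feature_chrom",
                                       "feature_start", "feature_end",
                                       "overlap_length"])


def detect_cgi(sequence: str, min_length: int = 200, min_gc: float = 0.5,
               min_obs_exp: float = 0.6) -> list[tuple[int, int]]:
    """CpG islands: maximal runs of qualifying fixed-length windows.

    A window of ``min_length`` bases qualifies when GC fraction >
    ``min_gc`` and observed/expected CpG >= ``min_obs_exp``, where
    expected = (#C * #G) / effective length. N bases are excluded from
    all counts and from the effective length. Qualifying windows (1-bp
    step) are merged into maximal intervals.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < min_length:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & (arr[1:] == ord("G"))

    def wsum(x):
        c = np.concatenate([[0], np.cumsum(x)])
        return c[min_length:] - c[:-min_length]

    c_cnt, g_cnt, n_cnt = wsum(is_c), wsum(is_g), wsum(is_n)
    # CpG pairs fully inside the window: starts i .. i+L-2
    ccpg = np.concatenate([[0], np.cumsum(is_cpg)])
    cpg_cnt = ccpg[min_length - 1:n - 1 + 1] - ccpg[: n - min_length + 1]
    eff_len = min_length - n_cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_frac = np.where(eff_len > 0, (c_cnt + g_cnt) / eff_len, 0.0)
        expected = np.where(eff_len > 0, c_cnt * g_cnt / eff_len, 0.0)
        obs_exp = np.where(expected > 0, cpg_cnt / expected, 0.0)
    ok = (gc_frac > min_gc) & (obs_exp >= min_obs_exp) & (eff_len > 0)
    islands: list[tuple[int, int]] = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            islands.append((i, j + min_length))
            i = j + 1
        i += 1
    return islands


def element_in_cgi(element: GenomicInterval, islands,
                   offset: int = 0) -> tuple[bool, float]:
    """Whether an element overlaps any CpG island, with overlap fraction.

    ``islands`` are (start, end) pairs in the same coordinate frame as
    the element minus ``offset`` (use offset = the sequence's genomic
    start when islands came from :func:`detect_cgi` on a subsequence).
    """
    covered = 0
    for s, e in islands:
        covered += max(0, min(element.end, e + offset)
                       - max(element.start, s + offset))
    return covered > 0, covered / len(element)
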