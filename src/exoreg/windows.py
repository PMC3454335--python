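"""Sliding-window empirical-null tests for per-base score tracks.

For a candidate element of length L inside a host gene, the null
distribution is the set of means of every length-L window slid in 1-bp
steps along the gene's concatenated exonic sequence (T bases, giving
T - L + 1 windows). The element's own window mean is compared to that
null as an empirical two-sided percentile; alternatively the element's
per-base scores can be compared to all other exonic bases with a
rank-sum test. The same machinery serves conservation scores and GC
indicator tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, GeneModel, GenomicInterval, ScoreTrack
from .stats import bh_fdr, wilcoxon_rank_sum

__all__ = [
    "concat_exonic_track",
    "window_scores",
    "element_vs_host_test",
    "gc_indicator_track",
    "classify_conservation",
    "batch_element_tests",
    "WindowNullResult",
]


def concat_exonic_track(gene: GeneModel, track: ScoreTrack
                        ) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Concatenate per-base scores over the gene's exons in transcript order.

    Returns (scores, coordinate map); map[i] is the (chrom, genomic
    position) of concatenated index i. Missing track coverage inside any
    exon raises :class:`DataError`.
    """
    scores: list[np.ndarray] = []
    coords: list[tuple[str, int]] = []
    for e in gene.exons:
        iv = e.interval
        vals = track.values(iv.chrom, iv.start, iv.end)
        positions = list(range(iv.start, iv.end))
        if gene.strand == "-":
            vals = vals[::-1]
            positions = positions[::-1]
        scores.append(vals)
        coords.extend((iv.chrom, p) for p in positions)
    return np.concatenate(scores), coords


def window_scores(scores: np.ndarray, length: int) -> np.ndarray:
    """Means of every length-``length`` window (1-bp step).

    Output has T - length + 1 entries; entry i is mean(scores[i:i+length]).
    NaN entries (masked bases) are ignored within each window.
    """
    arr = np.asarray(scores, dtype=float)
    if length < 1 or length > arr.size:
        raise DataError("window length must be in 1..len(scores)")
    mask = np.isfinite(arr)
    filled = np.where(mask, arr, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    cnt = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
    totals = csum[length:] - csum[:-length]
    counts = cnt[length:] - cnt[:-length]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, totals / counts, np.nan)


@dataclass
class WindowNullResult:
    element_id: str
    element_score: float
    n_windows: int
    p_value: float
    direction: str  # higher | lower
    q_value: float | None = None
    method: str = "window_rank"
    null_scores: np.ndarray | None = None


def element_vs_host_test(element_start: int, element_length: int,
                         scores: np.ndarray, mode: str = "window_rank",
                         element_id: str = "element",
                         exclude_element_windows: bool = False,
                         keep_null: bool = False) -> WindowNullResult:
    """Test an element's scores against its host gene's empirical null.

    ``element_start`` indexes the concatenated exonic axis. Modes:

    * ``window_rank`` (default): the element's window mean is ranked
      among all window means; two-sided empirical p = 2 * min(fraction of
      windows >= element, fraction <= element), capped at 1. The element's
      own window is part of the reference set (so p >= 1/n_windows)
      unless ``exclude_element_windows`` removes windows overlapping the
      element (the element itself then counts once, add-one style).
    * ``basewise_ranksum``: Wilcoxon rank-sum of element per-base scores
      against all other exonic bases.
    """
    arr = np.asarray(scores, dtype=float)
    t = arr.size
    length = element_length
    if element_start < 0 or element_start + length > t:
        raise DataError("element does not lie within the concatenated axis")
    elem_vals = arr[element_start:element_start + length]
    if not np.all(np.isfinite(elem_vals)):
        raise DataError("element overlaps track gaps / masked bases")
    elem_mean = float(np.nanmean(elem_vals))

    if mode == "window_rank":
        wins = window_scores(arr, length)
        n_windows = wins.size
        if exclude_element_windows:
            idx = np.arange(n_windows)
            keep = (idx + length <= element_start) | (idx >= element_start + length)
            null = wins[keep]
            ge = 1 + int(np.sum(null >= elem_mean - 1e-12))
            le = 1 + int(np.sum(null <= elem_mean + 1e-12))
            denom = null.size + 1
        else:
            null = wins
            ge = int(np.sum(null >= elem_mean - 1e-12))
            le = int(np.sum(null <= elem_mean + 1e-12))
            denom = n_windows
        p = min(1.0, 2.0 * min(ge, le) / denom)
        direction = "higher" if ge <= le else "lower"
        return WindowNullResult(
            element_id=element_id, element_score=elem_mean,
            n_windows=n_windows, p_value=p, direction=direction,
            method="window_rank",
            null_scores=(wins if keep_null else None))
    if mode == "basewise_ranksum":
        other = np.delete(arr, np.s_[element_start:element_start + length])
        other = other[np.isfinite(other)]
        res = wilcoxon_rank_sum(elem_vals, other)
        direction = ("higher" if np.nanmean(elem_vals) > np.nanmean(other)
                     else "lower")
        return WindowNullResult(
            element_id=element_id, element_score=elem_mean,
            n_windows=t - length + 1, p_value=res.p_value, direction=direction,
            method="basewise_ranksum")
    raise ValueError(f"unknown mode {mode!r}")


def gc_indicator_track(sequence: str) -> np.ndarray:
    """Per-base GC indicator: G/C -> 1, A/T -> 0, N -> NaN (masked)."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.where((arr == ord("G")) | (arr == ord("C")), 1.0, 0.0)
    out[(arr != ord("G")) & (arr != ord("C")) & (arr != ord("A"))
        & (arr != ord("T"))] = np.nan
    return out


def classify_conservation(mean_score: float) -> str:
    """Conservation category from the element's mean per-base score.

    > 0.5 strongly conserved; (0.1, 0.5] somewhat conserved; <= 0.1 not
    conserved.
    """
    if mean_score > 0.5:
        return "strongly"
    if mean_score > 0.1:
        return "somewhat"
    return "not_conserved"


def _element_on_axis(element: GenomicInterval, coords) -> tuple[int, int]:
    index = {c: i for i, c in enumerate(coords)}
    positions = [index.get((element.chrom, p))
                 for p in range(element.start, element.end)]
    if any(p is None for p in positions):
        raise DataError("element extends outside the gene's exons")
    positions = sorted(positions)
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise DataError("element is not contiguous on the exonic axis")
    return positions[0], len(positions)


def batch_element_tests(elements: dict[str, tuple[GenomicInterval, GeneModel]],
                        tracks: dict[str, ScoreTrack],
                        mode: str = "window_rank",
                        exclude_element_windows: bool = False
                        ) -> list[WindowNullResult]:
    """Run element-vs-host tests for a panel and BH-correct across it.

    ``elements`` maps element_id -> (interval, host gene); ``tracks``
    maps gene_id -> ScoreTrack (a single shared track may be passed for
    every gene). q-values are computed across the whole element set.
    """
    results: list[WindowNullResult] = []
    for eid, (interval, gene) in elements.items():
        track = tracks[gene.gene_id] if gene.gene_id in tracks else tracks[eid]
        scores, coords = concat_exonic_track(gene, track)
        start, length = _element_on_axis(interval, coords)
        results.append(element_vs_host_test(
            start, length, scores, mode=mode, element_id=eid,
            exclude_element_windows=exclude_element_windows))
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
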