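"""Population-diversity comparison of elements vs host-gene exons.

Segregating common SNVs (MAF > 1%) are counted per base pair inside each
element and over the rest of its host gene's exons; paired element-host
rate differences are tested with the Wilcoxon signed-rank test. Coding
variants are split into synonymous and nonsynonymous by strand-aware
codon translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .core import (
    DataError,
    GeneModel,
    GenomicInterval,
    VariantRecord,
    merge_intervals,
    subtract_intervals,
)
from .stats import TestResult, wilcoxon_signed_rank

__all__ = [
    "filter_by_maf",
    "classify_consequence",
    "substitution_rate",
    "compare_rates",
    "RateComparison",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def filter_by_maf(variants, maf_min: float = 0.01) -> list[VariantRecord]:
    """Retain usable biallelic SNVs with MAF strictly greater than maf_min."""
    return [v for v in variants if v.usable and v.maf > maf_min]


def _spliced_cds(gene: GeneModel, sequence: str) -> str:
    """CDS sequence 5'->3' (reverse-complemented for minus-strand genes)."""
    parts = []
    for iv in gene.cds_intervals():
        sub = sequence[iv.start:iv.end]
        parts.append(sub.translate(_COMPLEMENT)[::-1] if gene.strand == "-" else sub)
    return "".join(parts)


def classify_consequence(variant: VariantRecord, gene: GeneModel,
                         sequence: str) -> str:
    """Coding consequence of an SNV within its host gene.

    CDS variants are classified by translating the reference and mutated
    codons (standard nuclear code, strand-aware): same amino acid ->
    ``synonymous``, else ``nonsynonymous``. UTR and noncoding-exon
    variants are ``noncoding``. A variant in a trailing partial codon is
    ``unassigned``. The FASTA base must match the variant's REF allele.
    """
    if sequence[variant.pos] != variant.ref:
        raise DataError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"VCF {variant.ref} vs FASTA {sequence[variant.pos]}")
    kind = gene.kind_at(variant.chrom, variant.pos)
    if kind is None:
        raise DataError(
            f"variant {variant.chrom}:{variant.pos} not exonic in {gene.gene_id}")
    if kind != "cds":
        return "noncoding"
    cds_off = gene.cds_offset(variant.pos)
    idx = cds_off - gene.cds_frame_offset
    if idx < 0:
        return "unassigned"
    codon_i = idx // 3
    cds = _spliced_cds(gene, sequence)
    start = gene.cds_frame_offset + 3 * codon_i
    codon = cds[start:start + 3]
    if len(codon) < 3:
        return "unassigned"
    ref_base, alt_base = variant.ref, variant.alt
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    within = idx % 3
    if codon[within] != ref_base:
        raise DataError("internal codon/REF inconsistency")
    mutated = codon[:within] + alt_base + codon[within + 1:]
    return ("synonymous"
            if Seq(codon).translate() == Seq(mutated).translate()
            else "nonsynonymous")


def substitution_rate(intervals, variants) -> float:
    """Segregating sites per base pair over a set of intervals."""
    merged = merge_intervals(intervals)
    total = sum(len(iv) for iv in merged)
    if total == 0:
        raise DataError("substitution_rate over empty intervals")
    count = sum(
        1 for v in variants
        if any(iv.contains(v.chrom, v.pos) for iv in merged)
    )
    return count / total


@dataclass
class RateComparison:
    """Paired element-vs-host substitution rates and their signed-rank test."""

    element_rates: dict[str, float]
    host_rates: dict[str, float]
    median_element: float
    median_host: float
    signed_rank: TestResult
    stratum: str = "all"
    n_pairs: int = 0


def _stratum_intervals(gene: GeneModel, stratum: str) -> list[GenomicInterval]:
    if stratum == "all":
        return gene.exonic_intervals
    return gene.cds_intervals()


def compare_rates(elements: dict[str, tuple[GenomicInterval, GeneModel]],
                  variants, sequences: dict[str, str] | None = None,
                  stratum: str = "all", maf_min: float = 0.01,
                  signed_rank_method: str = "approx") -> RateComparison:
    """Compare per-bp substitution rates of elements to their host exons.

    ``elements`` maps element_id -> (interval, host gene). For the
    ``synonymous``/``nonsynonymous`` strata, variants are first
    classified per host gene (``sequences`` required) and only CDS bases
    enter the denominators; the element's own bases are always excluded
    from the host denominator. Zero paired differences are dropped by the
    signed-rank test, so N_r can be smaller than the number of elements.
    """
    if stratum not in {"all", "synonymous", "nonsynonymous"}:
        raise DataError(f"unknown stratum {stratum!r}")
    if stratum != "all" and sequences is None:
        raise DataError("consequence strata require sequences")
    kept = filter_by_maf(variants, maf_min)
    element_rates: dict[str, float] = {}
    host_rates: dict[str, float] = {}
    for eid, (interval, gene) in elements.items():
        domain = _stratum_intervals(gene, stratum)
        if stratum == "all":
            vs = [v for v in kept if v.chrom == gene.chrom]
        else:
            vs = []
            for v in kept:
                if v.chrom != gene.chrom or gene.kind_at(v.chrom, v.pos) != "cds":
                    continue
                cons = v.consequence or classify_consequence(
                    v, gene, sequences[gene.chrom])
                if cons == stratum:
                    vs.append(v)
        elem_domain = [
            GenomicInterval(iv.chrom, max(iv.start, interval.start),
                            min(iv.end, interval.end))
            for iv in domain
            if iv.overlap_length(interval) > 0
        ]
        host_domain = subtract_intervals(domain, [interval])
        if not elem_domain or not host_domain:
            # e.g. a UTR-resident element has no CDS bases: it cannot enter
            # a synonymous/nonsynonymous comparison
            continue
        element_rates[eid] = substitution_rate(elem_domain, vs)
        host_rates[eid] = substitution_rate(host_domain, vs)
    if not element_rates:
        raise DataError(f"no element has a non-empty {stratum!r} domain")
    ids = sorted(element_rates)
    diffs = np.array([element_rates[i] - host_rates[i] for i in ids])
    test = wilcoxon_signed_rank(diffs, method=signed_rank_method)
    return RateComparison(
        element_rates=element_rates,
        host_rates=host_rates,
        median_element=float(np.median([element_rates[i] for i in ids])),
        median_host=float(np.median([host_rates[i] for i in ids])),
        signed_rank=test,
        stratum=stratum,
        n_pairs=len(ids),
    )
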