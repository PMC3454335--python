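"""Synthetic-data generators with known ground truth.

Every generator is a pure function of (config, seed): the same arguments
give byte-identical outputs. The generators emulate the four input
classes the pipeline consumes — dual-reporter plate screens, exonic loci
with per-base conservation tracks and sequence, population variants, and
2x2 factorial expression designs — with truth tables that record what was
injected, so recovery and calibration are testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    DataError,
    FactorialExpressionSet,
    GeneModel,
    GenomicInterval,
    ScoreTrack,
    TypedExon,
    VariantRecord,
)

BASES = np.array(list("ACGT"))

# Control-well activity levels on the log10 firefly/Renilla scale, chosen to
# reproduce the expected control hierarchy: promoterless vectors low,
# promoter-only moderate (the screen's reference, set to 0), and the
# positive liver enhancer high.
CONTROL_ACTIVITY = {"no_promoter": -1.5, "promoter_only": 0.0,
                    "positive_enhancer": 1.0}


@dataclass
class ScreenConfig:
    """Study conditions for the reporter screen simulation.

    Baseline (neutral-clone) screen noise is a left-skewed skew-normal on
    log10 activity — nearly normal with an extended negative tail. Effects
    are additive log10 shifts; enhancers get modest positive shifts and
    silencers a wider negative range, matching the silencer-heavy outcome
    of the assay this emulates.
    """

    n_clones: int = 1000
    n_plates: int = 6  # assay batches; 3 per digestion enzyme
    n_enhancers: int = 5
    n_silencers: int = 15
    enhancer_effect: tuple[float, float] = (0.5, 1.0)
    silencer_effect: tuple[float, float] = (0.5, 2.0)  # magnitudes; applied negative
    skew_shape: float = -4.0
    skew_scale: float = 0.2
    plate_sd: float = 0.15
    replicate_sd: float = 0.1
    n_round1: int = 3
    n_round2: int = 8
    n_control_wells: int = 2  # per role per plate
    n_reference_replicates: int = 8  # promoter-only wells per round
    renilla_log_mean: float = 7.0
    renilla_log_sd: float = 0.3


@dataclass
class ScreenSimulation:
    plates: pd.DataFrame      # initial screen wells (one well per clone)
    round1: pd.DataFrame      # replicate assays, all experimental clones
    round2: pd.DataFrame
    truth: pd.DataFrame       # clone_id, true_class, true_effect
    config: ScreenConfig


def _signals(rng, activities, cfg: ScreenConfig):
    """Back-compute firefly/Renilla pairs from log10 activities."""
    renilla = np.exp(rng.normal(cfg.renilla_log_mean, cfg.renilla_log_sd,
                                size=len(activities)))
    firefly = renilla * 10.0 ** np.asarray(activities)
    return firefly, renilla


def simulate_screen(config: ScreenConfig | None = None, *, seed: int) -> ScreenSimulation:
    """Simulate the initial plate screen plus two replicate assay rounds.

    The initial screen observes, per clone, true_effect + plate effect +
    skew-normal well noise. Replicate rounds observe true_effect +
    Gaussian noise (sd ``replicate_sd``) relative to the promoter-only
    reference, for every experimental clone, so any candidate subset can
    be confirmed from the same tables.
    """
    cfg = config or ScreenConfig()
    if cfg.n_clones < 1:
        raise DataError("n_clones must be >= 1")
    n_spiked = cfg.n_enhancers + cfg.n_silencers
    if n_spiked > cfg.n_clones:
        raise DataError("more spiked clones than clones")
    rng = np.random.default_rng(seed)

    clone_ids = np.array([f"c{i:05d}" for i in range(cfg.n_clones)])
    enzymes = np.where(np.arange(cfg.n_clones) % 2 == 0, "Sau3AI", "AluI")
    plate_of = np.arange(cfg.n_clones) % cfg.n_plates
    # keep each plate single-enzyme: even plates Sau3AI, odd AluI
    plate_of = np.where(enzymes == "Sau3AI",
                        (np.arange(cfg.n_clones) // 2) % max(cfg.n_plates // 2, 1) * 2,
                        (np.arange(cfg.n_clones) // 2) % max(cfg.n_plates // 2, 1) * 2 + 1)

    true_effect = np.zeros(cfg.n_clones)
    true_class = np.full(cfg.n_clones, "neutral", dtype=object)
    spiked = rng.choice(cfg.n_clones, size=n_spiked, replace=False)
    enh, sil = spiked[: cfg.n_enhancers], spiked[cfg.n_enhancers:]
    true_effect[enh] = rng.uniform(*cfg.enhancer_effect, size=enh.size)
    true_effect[sil] = -rng.uniform(*cfg.silencer_effect, size=sil.size)
    true_class[enh] = "enhancer"
    true_class[sil] = "silencer"

    # centred skew-normal well noise for the single-well initial screen
    delta = cfg.skew_shape / np.sqrt(1 + cfg.skew_shape**2)
    skew_mean = cfg.skew_scale * delta * np.sqrt(2 / np.pi)
    noise = sps.skewnorm.rvs(cfg.skew_shape, scale=cfg.skew_scale,
                             size=cfg.n_clones, random_state=rng) - skew_mean
    plate_effect = rng.normal(0.0, cfg.plate_sd, size=cfg.n_plates)
    activity = true_effect + plate_effect[plate_of] + noise
    firefly, renilla = _signals(rng, activity, cfg)

    rows = {
        "clone_id": clone_ids, "batch_id": [f"P{p:02d}" for p in plate_of],
        "enzyme": enzymes, "well_role": "experimental",
        "firefly": firefly, "renilla": renilla,
    }
    plates = pd.DataFrame(rows)
    ctrl_rows = []
    for p in range(cfg.n_plates):
        for role, level in CONTROL_ACTIVITY.items():
            acts = level + plate_effect[p] + rng.normal(
                0.0, cfg.replicate_sd, size=cfg.n_control_wells)
            ff, rr = _signals(rng, acts, cfg)
            for k in range(cfg.n_control_wells):
                ctrl_rows.append(
                    {"clone_id": f"{role}_{p}_{k}", "batch_id": f"P{p:02d}",
                     "enzyme": "control", "well_role": role,
                     "firefly": ff[k], "renilla": rr[k]})
    plates = pd.concat([plates, pd.DataFrame(ctrl_rows)], ignore_index=True)

    def replicate_round(n_rep: int) -> pd.DataFrame:
        recs = []
        for cid, eff in zip(clone_ids, true_effect):
            acts = eff + rng.normal(0.0, cfg.replicate_sd, size=n_rep)
            ff, rr = _signals(rng, acts, cfg)
            for k in range(n_rep):
                recs.append({"clone_id": cid, "batch_id": "round",
                             "enzyme": "control", "well_role": "experimental",
                             "firefly": ff[k], "renilla": rr[k]})
        acts = rng.normal(0.0, cfg.replicate_sd, size=cfg.n_reference_replicates)
        ff, rr = _signals(rng, acts, cfg)
        for k in range(cfg.n_reference_replicates):
            recs.append({"clone_id": f"promoter_only_{k}", "batch_id": "round",
                         "enzyme": "control", "well_role": "promoter_only",
                         "firefly": ff[k], "renilla": rr[k]})
        df = pd.DataFrame(recs)
        df["enzyme"] = np.where(df["well_role"] == "experimental",
                                pd.Series(enzymes, index=clone_ids).reindex(
                                    df["clone_id"]).fillna("control").values,
                                "control")
        return df

    round1 = replicate_round(cfg.n_round1)
    round2 = replicate_round(cfg.n_round2)
    truth = pd.DataFrame({"clone_id": clone_ids, "true_class": true_class,
                          "true_effect": true_effect})
    return ScreenSimulation(plates=plates, round1=round1, round2=round2,
                            truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# loci with conservation tracks


@dataclass
class LocusConfig:
    """Study conditions for one synthetic host gene.

    Per-base conservation scores are Beta-distributed: background mean
    ``background_mean``; element bases get mean background_mean +
    ``conservation_lift`` (clipped to (0, 1)). GC content is controllable
    per region via base-composition probabilities.
    """

    n_exons: int = 5
    exon_length: int = 300
    intron_length: int = 200
    flank: int = 100
    element_length: int = 167
    background_mean: float = 0.2
    conservation_lift: float = 0.7
    concentration: float = 5.0
    background_gc: float = 0.45
    element_gc: float = 0.45
    chrom: str = "chrS"
    strand: str = "+"
    gene_id: str = "geneS"
    coding: bool = True
    element_exon: int | None = None  # pin the element's host exon (genomic order)


@dataclass
class LocusTruth:
    gene: GeneModel
    element_interval: GenomicInterval
    conservation_lift: float
    snp_density_multiplier: float = 1.0


@dataclass
class LocusSimulation:
    gene: GeneModel
    sequence: dict[str, str]
    track: ScoreTrack
    truth: LocusTruth
    config: LocusConfig


def _draw_beta(rng, mean: float, conc: float, size: int) -> np.ndarray:
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    return rng.beta(mean * conc, (1 - mean) * conc, size=size)


def _draw_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def simulate_locus(config: LocusConfig | None = None, *, seed: int) -> LocusSimulation:
    """Simulate a host gene, its sequence, and a per-base score track.

    The regulatory element is one contiguous genomic window placed inside
    a single (uniformly chosen, long-enough) exon. Scores cover exons
    only, as a conservation track consumed exon-wise would.
    """
    cfg = config or LocusConfig()
    rng = np.random.default_rng(seed)
    if cfg.element_length > cfg.n_exons * cfg.exon_length:
        raise DataError("element longer than total exonic length")
    if cfg.element_length > cfg.exon_length:
        raise DataError(
            "element longer than every exon (elements are contiguous windows)"
        )
    exon_starts = [
        cfg.flank + i * (cfg.exon_length + cfg.intron_length)
        for i in range(cfg.n_exons)
    ]
    chrom_len = exon_starts[-1] + cfg.exon_length + cfg.flank
    exons = [GenomicInterval(cfg.chrom, s, s + cfg.exon_length, cfg.strand)
             for s in exon_starts]

    if cfg.coding:
        kinds = ["cds"] * cfg.n_exons
        kinds[0] = "utr5" if cfg.strand == "+" else "utr3"
        kinds[-1] = "utr3" if cfg.strand == "+" else "utr5"
        # keep CDS in frame by trimming is unnecessary: frame offset 0 and the
        # consequence classifier flags trailing partial codons
        typed = [TypedExon(iv, k) for iv, k in zip(exons, kinds)]
    else:
        typed = [TypedExon(iv, "noncoding_exon") for iv in exons]
    if cfg.strand == "-":
        typed = typed[::-1]
    gene = GeneModel(cfg.gene_id, cfg.chrom, cfg.strand, typed)

    # place the element inside one exon chosen uniformly among those that fit
    exon_idx = (cfg.element_exon if cfg.element_exon is not None
                else int(rng.integers(0, cfg.n_exons)))
    host_exon = exons[exon_idx]
    lo = host_exon.start
    hi = host_exon.end - cfg.element_length
    e_start = int(rng.integers(lo, hi + 1))
    element = GenomicInterval(cfg.chrom, e_start, e_start + cfg.element_length,
                              cfg.strand)

    seq = _draw_seq(rng, chrom_len, cfg.background_gc)
    seq[element.start:element.end] = _draw_seq(rng, len(element), cfg.element_gc)

    track = ScoreTrack()
    for iv in exons:
        vals = _draw_beta(rng, cfg.background_mean, cfg.concentration, len(iv))
        track.add_segment(cfg.chrom, iv.start, vals)
    if cfg.conservation_lift != 0.0:
        lifted = _draw_beta(rng, cfg.background_mean + cfg.conservation_lift,
                            cfg.concentration, len(element))
        # replace in place within the covered segment
        seg_vals = track.values(cfg.chrom, element.start, element.end)
        del seg_vals
        for seg_start, arr in track.segments(cfg.chrom):
            if seg_start <= element.start < seg_start + arr.size:
                arr[element.start - seg_start:element.end - seg_start] = lifted

    truth = LocusTruth(gene=gene, element_interval=element,
                       conservation_lift=cfg.conservation_lift)
    return LocusSimulation(gene=gene, sequence={cfg.chrom: "".join(seq)},
                           track=track, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# variants


@dataclass
class VariantConfig:
    """Poisson SNV placement with a Beta MAF law.

    ``site_density`` is the per-exonic-base probability of a segregating
    site; inside the element it is multiplied by ``multiplier`` in [0, 1]
    (reduced diversity). MAFs are 0.5 * Beta(a, b), a decreasing law that
    puts most sites at low frequency.
    """

    site_density: float = 0.003
    multiplier: float = 0.3
    maf_beta: tuple[float, float] = (0.5, 1.5)


def simulate_variants(locus: LocusSimulation, config: VariantConfig | None = None,
                      *, seed: int) -> list[VariantRecord]:
    """Place SNVs over the locus's exonic bases; REF matches the FASTA."""
    cfg = config or VariantConfig()
    if not 0.0 <= cfg.multiplier <= 1.0:
        raise DataError("multiplier must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = locus.sequence[locus.gene.chrom]
    element = locus.truth.element_interval
    records: list[VariantRecord] = []
    for iv in sorted(locus.gene.exonic_intervals, key=lambda v: v.start):
        positions = np.arange(iv.start, iv.end)
        inside = (positions >= element.start) & (positions < element.end)
        dens = np.where(inside, cfg.site_density * cfg.multiplier,
                        cfg.site_density)
        hits = positions[rng.random(positions.size) < dens]
        for pos in hits:
            ref = seq[pos]
            if ref not in "ACGT":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            maf = 0.5 * rng.beta(*cfg.maf_beta)
            records.append(VariantRecord(chrom=iv.chrom, pos=int(pos),
                                         ref=ref, alt=str(alt), maf=float(maf)))
    locus.truth.snp_density_multiplier = cfg.multiplier
    return records


# ---------------------------------------------------------------------------
# factorial expression


@dataclass
class ExpressionConfig:
    """2x2 genotype x treatment design (or a two-group design).

    The competition model this emulates: the treatment activates a
    repressor that binds the target's exonic silencer, so the target mean
    drops by ``repression_effect`` only in the (wild_type, treated) cell;
    in the two-group design a dominant-negative allele of an activator
    lowers the target. The control gene is unaffected everywhere.
    """

    design: str = "2x2"  # or "two_group"
    n_per_cell: int = 3
    target_gene: str = "TUBA1B"
    control_gene: str = "TUBB4"
    baseline: float = 10.0
    repression_effect: float = 1.0  # log2 units
    noise_sd: float = 0.2
    genotype_levels: tuple[str, str] = ("wild_type", "null")
    treatment_levels: tuple[str, str] = ("vehicle", "agonist")


def simulate_factorial_expression(config: ExpressionConfig | None = None,
                                  *, seed: int) -> FactorialExpressionSet:
    """Simulate expression for a target and a control gene."""
    cfg = config or ExpressionConfig()
    rng = np.random.default_rng(seed)
    wt, other = cfg.genotype_levels
    genes = [cfg.target_gene, cfg.control_gene]
    if cfg.design == "2x2":
        veh, trt = cfg.treatment_levels
        samples, genos, treats = [], [], []
        for g in (wt, other):
            for t in (veh, trt):
                for k in range(cfg.n_per_cell):
                    samples.append(f"{g}_{t}_{k}")
                    genos.append(g)
                    treats.append(t)
        factors = pd.DataFrame({"genotype": genos, "treatment": treats},
                               index=samples)
        means = np.full((2, len(samples)), cfg.baseline)
        hit = [(g == wt and t == trt) for g, t in zip(genos, treats)]
        means[0, np.array(hit)] -= cfg.repression_effect
    elif cfg.design == "two_group":
        samples, genos = [], []
        for g in (wt, other):
            for k in range(cfg.n_per_cell):
                samples.append(f"{g}_{k}")
                genos.append(g)
        factors = pd.DataFrame({"genotype": genos}, index=samples)
        means = np.full((2, len(samples)), cfg.baseline)
        means[0, np.array(genos) == other] -= cfg.repression_effect
    else:
        raise DataError(f"unknown design {cfg.design!r}")
    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    mat = pd.DataFrame(values, index=genes, columns=samples)
    return FactorialExpressionSet(values=mat, factors=factors)
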