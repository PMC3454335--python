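# Methods

This note documents the models, statistical dialects, and design
choices behind `exoreg`, in the spirit of a package methods appendix:
what is computed, under which assumptions, and what the synthetic
benchmarks do and do not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention). The two
1-based formats the pipeline reads — VCF `POS` and fixed-step wiggle
`start` — are converted at the I/O boundary, once, with boundary
positions covered by explicit tests. Plate tables are CSV with a fixed
six-column vocabulary; wells whose signals cannot yield a log-ratio
(Renilla ≤ 0) are *flagged* unusable rather than dropped, so downstream
stages, not the parser, decide their fate.

## Screening statistics

**Activity.** a = log10(firefly / Renilla). The Renilla channel controls
for transfection efficiency; on the log scale it cancels exactly in the
simulation's generative model (firefly = Renilla · 10^activity · noise),
which makes the log-ratio the natural recovered quantity.

**Quantile normalization.** Within each digestion-enzyme group, the
reference distribution is the across-batch mean quantile function; for
equal batch sizes this is exactly the mean of batch-sorted vectors, and
unequal sizes are handled by linear quantile interpolation. Tied values
receive the mean of their tied reference quantiles. Control wells are
excluded from the reference set (they are few, non-random, and would
distort the tails) but are mapped through their batch's fitted quantile
map by interpolation. An enzyme group with a single batch passes through
unchanged with a warning. Normalization is idempotent.

**Candidate gate.** Clones beyond mean ± 2·SD of the normalized
experimental activities, per enzyme group, both tails. The sample SD is
taken over experimental clones only. A zero-spread group selects nothing
(warning).

**Confirmation.** Each candidate's replicate activities (round 1: n = 3,
round 2: n = 8) are tested with a two-sided one-sample t (df = n − 1)
against the round's reference, the mean activity of promoter-only wells
pooled across that round's plates (pooled rather than per-plate for
stability at few wells per plate; exposed as the natural point to
change). BH correction is applied across candidates *within each round*,
gate q < 0.05; round 2 runs only for round-1 passers; confirmation also
requires the same effect sign in both rounds. Confirmed clones are
classified enhancer/silencer by the sign of the round-2 mean relative to
the reference. Stage outputs are nested subsets by construction.

## Statistical dialects

* **Two-sample t** is the pooled-variance Student form, df = n1 + n2 − 2
  (not Welch) — the convention the downstream post-hoc analyses assume.
* **2×2 ANOVA** is balanced-only: SS decomposition with df = 1 per
  effect, error df = N − 4, F = MS_effect / MS_error. Unbalanced designs
  are rejected rather than silently switching to a Type-I/II convention.
* **Wilcoxon signed-rank**: zero differences dropped (N_r counts the
  rest), |d| ranked with average ranks on ties,
  W = Σ ranks of positive differences, and

      z = (|W − μ| − 0.5) / σ,   μ = N_r(N_r+1)/4,
      σ² = N_r(N_r+1)(2N_r+1)/24 − Σ(t³−t)/48,

  two-sided p = 2·Φ(−z). The continuity-corrected normal approximation
  is the default even at small N_r because the published operating
  points this package targets are computed in that dialect (exact
  enumeration gives different values); exact enumeration over sign
  assignments is available via `method="exact"`. One published triple
  (W = 30, N_r = 8, p = 0.1069) differs from this dialect's 0.1073 by an
  amount consistent with a single tied |difference| pair in the original
  (unavailable) data; we document rather than force-match it.
* **Wilcoxon rank-sum**: exact by full enumeration when n1 + n2 ≤ 12
  with no ties, otherwise tie-corrected normal with continuity
  correction.
* **BH q-values**: step-up q_i = min_{j≥i} p_(j)·m/j, capped at 1,
  min-monotone by construction.

## Sliding-window empirical null

For an element of length L in a host gene, scores are concatenated over
the gene's exons in transcript orientation (T bases; "expressed region"
read as mature exonic sequence — a flag for genomic-span mode is a
one-line change in `concat_exonic_track`). All T − L + 1 window means in
1-bp steps form the null. The default comparison ranks the element's own
window mean in that null (two-sided empirical p = 2·min(tail fractions),
element's window included, so p ≥ 1/n_windows): a rank-sum test with a
one-window sample degenerates to exactly this percentile. A per-base
rank-sum mode (`basewise_ranksum`, element bases vs all other exonic
bases) is provided because "comparing the element's values to the null"
is also readable base-wise; on high-lift benchmarks the two modes agree
in direction in ≥95% of seeds. Windows overlapping the element are kept
in the null by default (`exclude_element_windows` removes them,
switching to an add-one estimator). Note that the empirical p is
invariant to positive affine rescalings of the track for any L, and to
arbitrary monotone transforms only for L = 1 (window *means* do not
commute with nonlinear maps).

GC analyses reuse the same machinery on a 0/1 G|C indicator track with N
bases masked (NaN, ignored inside window means).

Mean element conservation is categorized strongly (>0.5), somewhat
(>0.1), or not conserved (≤0.1), with strict thresholds.

## CpG islands

Sliding 200-bp windows at 1-bp step qualify when GC fraction > 0.5 and
observed/expected CpG ≥ 0.6 with expected = (#C·#G)/length; qualifying
windows are merged into maximal intervals. N bases are excluded from all
counts and from the effective length. The published rule states criteria
but no algorithm; fixed-window merging is this package's convention and
is strand-symmetric (tested via reverse complement).

## Population diversity

Variants are restricted to usable biallelic SNVs with MAF strictly
greater than 1% (MAF = min(AF, 1 − AF); from genotypes, allele counts
over non-missing calls). The substitution rate of an interval set is
segregating sites per bp — unweighted by allele frequency, the simplest
reading of a count-based rate, and the only mode offered. For each
element the host denominator is the gene's exonic (or CDS, for
consequence strata) bases *minus* the element's own. Elements without
any base in a stratum's domain (e.g. a UTR element in a
synonymous-stratum comparison) are excluded from that comparison rather
than contributing an undefined rate. Paired element − host differences
feed the signed-rank test; zero differences dropping out explains
N_r < number of elements. Consequences come from strand-aware
translation of the reference and mutated codon (standard nuclear code);
stop-affecting changes count as nonsynonymous; partial trailing codons
are `unassigned`. The classifier is validated against an oracle that
translates the whole mutated CDS.

## Expression validation

Expression is analyzed on the provided (log) scale. The 2×2 analysis
applies the balanced ANOVA per gene, then pooled-variance post-hoc t
tests within each genotype, oriented (treated − untreated) so that
attenuation under treatment gives a negative t. The specificity check
declares a cis-effect "specific" when the target's treatment main effect
is significant at α and the negative-control gene's is not; the
treatment effect is used because it is the factor the perturbation
manipulates. A series-matrix parser (`read_series_matrix`) converts
public expression series files on disk into the matrix/factor pair, with
probe-to-gene collapse by highest mean expression (probe selection for
public series is ambiguous; this is the documented default and the main
reproducibility caveat for re-analyses of published arrays).

## Synthetic-data generators

Every generator is a pure function of (config, seed); identical calls
give byte-identical tables.

**Screen** (`simulate_screen`): neutral-clone screen noise is a
left-skewed skew-normal on log10 activity (shape −4, scale 0.2,
centred), reproducing a nearly normal, negatively skewed activity
distribution; additive batch effects (SD 0.15); control wells at
−1.5 / 0 / +1.0 log10 for promoterless / promoter-only / positive-
enhancer roles, giving the expected control hierarchy. Spiked effects
are additive log10 shifts: 5 enhancers U(0.5, 1.0) and 15 silencers
−U(0.5, 2.0) among 1,000 clones by default — silencer-heavy with a wider
negative effect range, matching the screen's qualitative outcome.
Replicate assays observe effect + N(0, 0.1) per replicate. The default
uses 6 assay batches (3 per enzyme, ~167 clones each): with many small
batches, quantile normalization shrinks a lone extreme clone toward the
mean of the other batches' spike-free tails, and the 2-SD gate loses
intermediate-effect spikes; three larger batches per enzyme is the
operating point at which the gate retains ≥90% of |effect| ≥ 0.5 spikes,
which is what the benchmark is designed to measure. What the benchmark
shows: the staged workflow recovers strong, persistent effects at
near-zero empirical FDR under this noise model. What it does not show:
robustness to plate-spatial artifacts, transfection-efficiency drift
beyond the Renilla ratio, or clones whose activity is real but below the
2-SD gate — all absent from the generative model.

**Locus** (`simulate_locus`): per-base conservation scores are Beta
draws (background mean 0.2, concentration 5); the element window's mean
is lifted by `conservation_lift` (default 0.7, clipped into (0, 1)).
Sequence GC is controllable per region. The element is one contiguous
genomic window inside a single exon (a contiguous interval cannot
straddle an intron); an element longer than every exon is an error.
Real conservation tracks are spatially autocorrelated; the iid Beta
background makes the window null better-behaved than reality, so the
calibration results bound the idealized, not the real, false-positive
rate.

**Variants** (`simulate_variants`): per-exonic-base Bernoulli placement
(≈ Poisson) at `site_density` (default 0.003/bp, the order of common-SNV
density in exons), multiplied by `multiplier` ∈ [0, 1] inside the
element; MAFs are 0.5·Beta(0.5, 1.5), a decreasing law putting most
sites at low frequency; REF always matches the FASTA. No linkage
disequilibrium is modeled.

**Expression** (`simulate_factorial_expression`): 2×2 genotype ×
treatment with n = 3 per cell (or a two-group design), Gaussian noise
SD 0.2 (log2); the target mean drops by `repression_effect` (default
1.0 log2) only in the wild-type × treated cell — the competition model
in which treatment activates a repressor whose binding site sits in the
target's exonic silencer — while the control gene is flat everywhere.
In the two-group design the dominant-negative genotype lowers the
target (loss of an activator).

## Numerical conventions

Two-sided empirical p-values are doubled minimal tails capped at 1.
Zero-variance inputs yield flagged results with no p-value, never a
silent 0 or 1 (except the defined cases: identical constant groups give
t = 0, p = 1; a fully tied rank-sum gives p = 1). Degenerate ANOVA with
zero error variance reports F = 0/∞ with a flag. Window comparisons use
a 1e-12 tolerance when counting ties of floating-point means.

## Problem sizes

The heavy calibration suites run at: 50 seeds × 1,000 clones for screen
recovery (plus 10 pure-null seeds), 200 seeds × 4 null loci and 200
high-lift loci for window-null calibration, and 1,500-base exonic axes
per locus — sizes at which the Monte-Carlo tolerances quoted in the
tests are meaningful while the whole suite stays fast.

## Known limitations

Alignment is consumed, not computed (no BLAT); no repeat masking or
liftover; VCF support is the biallelic-SNV subset (no phasing or
structural variants); no probe-level microarray preprocessing; the
window null assumes a fully covered score track over every exon.
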