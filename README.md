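# exoreg

Statistics and pipeline code for discovering **exonic transcriptional
regulatory elements** — enhancers and silencers that sit inside coding
exons and UTRs — from dual-reporter (firefly/*Renilla*) shotgun cloning
screens, and for characterizing the confirmed elements by genomic
context, evolutionary conservation, population diversity, and factorial
expression validation.

It is written for computational biologists who want the analysis side of
such a screen as reusable, tested components: every wet-lab or external
input (plate readouts, conservation tracks, population VCFs, perturbation
expression series) has a synthetic twin with known ground truth, so the
whole pipeline can be exercised and calibrated without downloads.

## What it computes

**Screening.** Regulatory activity of a cloned fragment is the
log<sub>10</sub> ratio of firefly to *Renilla* luciferase signal,
a = log10(F/R). Activities are quantile-normalized across plates
(separately per digestion enzyme, controls mapped through but excluded
from the reference set); candidates are wells with |a − mean| > 2·SD;
confirmation uses two replicate rounds (n = 3 then n = 8) of one-sample
t tests against the promoter-only control (df = n − 1), each gated at
Benjamini–Hochberg FDR < 5%, with the effect sign required to agree
across rounds. Confirmed fragments are classified enhancer (above the
control) or silencer (below).

**Context.** Best-alignment filtering to typed exons (CDS / 5′UTR /
3′UTR / noncoding), element location typing by majority base overlap,
feature-track overlap annotation (TFBS / DNase / histone / chromatin-state
BED tracks), and CpG-island detection (≥200 bp, GC > 50%, observed/expected
CpG ≥ 0.6).

**Conservation and GC content.** For an element of length L in a host
gene with T concatenated exonic bases, a sliding window of length L
(1-bp steps, T − L + 1 windows) builds the gene's empirical null of
window means; the element's mean conservation (or GC indicator) score is
ranked against it, two-sided, with BH correction across the element
panel. Mean phastCons-style scores are binned as strongly (>0.5),
somewhat (>0.1), or not conserved (≤0.1).

**Population diversity.** Common SNVs (MAF > 1%) are counted per bp
inside each element versus the rest of its host gene's exons; paired
differences go into a Wilcoxon signed-rank test (W = sum of
positive-difference ranks over N_r nonzero pairs, p via the
continuity-corrected normal approximation). Coding variants are split
synonymous / nonsynonymous by strand-aware codon translation.

**Expression validation.** 2×2 genotype × treatment ANOVA
(df = 1 per effect, error df = N − 4) with pooled-variance post-hoc t
tests within genotype (df = n1 + n2 − 2), a two-group t for one-factor
designs, and a negative-control-gene specificity check.

## Worked example

Simulate the default screen benchmark (1,000 clones in six batches, 20
spiked elements with |effect| ≥ 0.5 log10, replicate SD 0.1) and run the
full workflow:

```python
from exoreg import simulate as sim
from exoreg.screen import run_screen

s = sim.simulate_screen(seed=7)
calls, report = run_screen(s.plates, s.round1, s.round2)
print(report)
```

```
{'screened': 1000, 'selected': 36, 'exon_retained': 36,
 'round1_pass': 21, 'round2_pass': 20, 'enhancers': 5, 'silencers': 15}
```

1,000 clones were screened; 36 fell beyond the 2-SD gate; 21 passed the
three-replicate round and 20 the eight-replicate round at FDR < 5%. For
this seed all 20 confirmed calls are true spikes (5 enhancers, 15
silencers). Individual calls carry the round statistics:

```
c00005  silencer  mean activity -0.786  q1=7.9e-03  q2=2.6e-08
c00054  silencer  mean activity -1.858  q1=1.6e-03  q2=5.0e-09
```

Conservation of a synthetic element against its host gene (element mean
0.894 over a background of mean 0.2; 1,334 sliding windows):

```python
from exoreg.windows import batch_element_tests, classify_conservation

loc = sim.simulate_locus(seed=7)
res = batch_element_tests({"elem": (loc.truth.element_interval, loc.gene)},
                          {loc.gene.gene_id: loc.track})[0]
print(res.element_score, res.n_windows, res.p_value, res.direction)
# 0.894  1334  0.0015  higher          -> classify_conservation: "strongly"
```

The same machinery is driven from the shell via the `exoreg` CLI
(`simulate`, `screen`, `window-test`, `diversity`,
`validate-expression`); every subcommand reads and writes the standard
formats (CSV plate tables, BED/BED12, bedGraph/wiggle, FASTA, VCF, TSV).

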