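# Methods

## Overview

The package models a two-library NIPT design. A *smash* library fragments
plasma cfDNA to ~40–50 bp, randomly self-ligates the pieces into chimeric
molecules longer than 300 bp, and sequences them PE250, so each read carries
several genomic tags; tags are recovered from split alignments, filtered, and
binned for copy-number analysis. An *amplifet* library deep-sequences a
panel of common SNPs to estimate the fetal fraction. Everything upstream of
the statistics (the wet lab and the aligner) is emulated by the simulator
with explicit ground truth, so the analysis code can be validated exactly.

## Simulation model (`simkit`)

**Genome.** 24 toy chromosomes with lengths proportional to the human
genome, scaled 1/1000 by default (~3.1 Mb total). Sequence is drawn per
base with a sinusoidal GC landscape (baseline 0.41, amplitude 0.10, period
20 kb, per-chromosome phase) so that GC stratification downstream is
non-trivial. Repeats are modelled as 150 bp blocks flagged independently
with probability `repeat_fraction` (default 0.5, mirroring the roughly
half-genome extent of the RepeatMasker track); at 1/1000 scale repeat
elements cannot be drawn to physical size, so the block length is a
compromise between realistic tag-level overlap probability and track
granularity. A SNP panel (default 102 sites) is placed on autosomes outside
repeats with alternate-allele frequencies uniform in [0.40, 0.50]; each SNP
gets one 110 bp amplicon interval (≤ 140 bp).

**cfDNA.** Each fragment is fetal with probability `fetal_fraction`;
lengths are normal — maternal 166 ± 10 bp, fetal 143 ± 10 bp, truncated at
20 bp — reflecting the plasma fragmentomics of the two compartments.
Chromosomes are sampled proportional to length × copy number: a trisomy
contributes 3 fetal copies (rate factor 1.5) on one whole chromosome
(mosaicism is not modelled); a male fetus carries one X and one Y at half
weight; maternal DNA never maps to Y. The expected target-chromosome share
under trisomy is therefore elevated by ≈ 1 + ff/2.

**Fragmentation and size selection.** Each fragment of length L receives
Poisson(L/43.8 − 1) uniform cut points. Pieces are kept inside the
[40, 50] bp window with a *linear acceptance taper* across the window
(slope 0.65): a bead-based upper size cut is soft, and a hard window over
uniform cuts would pin the retained mean at ~44.8 bp no matter the cut
rate. The taper slope was calibrated once by Monte-Carlo so the retained
mean equals the 43.8 bp target; the calibration is part of the generator's
definition, not a tuning knob.

**Ligation and reads.** Pieces are consumed in random order, each with a
random orientation, and a molecule closes as soon as its total length
exceeds `chimera_min_len` (default 300 bp; the merge limit of PE250 pairs
is left configurable because a 20 bp minimum overlap implies ~480 bp while
unmerged pairs in practice indicate ≥ 460 bp). R1 is the first 250 bases of
the molecule's top strand, R2 the reverse complement of the last 250;
errors are substitutions only, since the method never calls base-level
variants from smash reads. No adapters, PCR duplicates or quality-score
realism are modelled.

**Truth SAM.** The first mapping pass is replaced by a writer that emits,
for each mate, one primary plus supplementary records per fully-contained
part, with soft-clip CIGARs, SA tags and per-record MAPQ. A configurable
share of parts (`nonunique_rate`, default 0.18 — the approximate fraction
of 40 bp tags that cannot be placed uniquely in a human genome) draws
MAPQ < 60. With default geometry (molecules ≤ ~360 bp) every part is fully
contained in at least one mate, which is what makes the round trip exact.
The "strict" re-verification of sub-read sequences against the reference is
an identity on this truth path and is not implemented separately.

**Amplicon counts.** Maternal genotypes follow Hardy–Weinberg at the panel
frequency; the fetus inherits one maternal and one paternal allele; depth
is Poisson (default mean 5000×, with an optional per-amplicon dropout
rate, default 0); the alternate-allele count is binomial at the plasma
mixture fraction with an optional substitution-error floor.

## Tag recovery and filtering (`smash_core`)

One fragment is emitted per aligned block of each primary or supplementary
record (secondary alignments and unmapped reads are ignored). Filters apply
in a fixed first-failing order: MAPQ < 60 → ≥ 1 bp overlap with a repeat →
≥ 1 bp overlap with an amplicon → second-pass supplementary/minus-strand
flags. One-bp overlap (rather than containment) matches RepeatMasker
convention; all exclusion thresholds are strict "less than", so equality
passes (MAPQ 60 kept, exactly 2,500,000 fragments kept, exactly 4% fetal
fraction kept). Identical (chrom, start, end) tags seen by both mates of
one pair are counted once in per-pair statistics: short chimeras are
covered by both 250 bp mates, so raw records double-count central tags.

Pair merging scans all overlaps from 250 down to 20 in innie and outie
geometry, scores mismatch density over the candidate overlap (N counts as a
mismatch), accepts the lowest density ≤ 0.20, breaks ties toward the larger
overlap, and reports the merged length len(R1)+len(R2)−overlap.

## Copy-number analysis (`aneuploidy`)

Bins tile each chromosome; the default bin size is genome_length/1000
(~3 kb on the toy genome, the analogue of ~50 kb bins on a human genome).
A fragment belongs to the bin containing its start. Corrections apply in a
fixed order:

1. **Peak** — per sample, bins above mean + 3 SD of the sample's nonzero
   bins are reset to the sample mean (one pass).
2. **GC** — bins stratified by GC rounded to 0.01; each stratum with ≥ 10
   bins is rescaled to the sample's global mean bin count.
3. **Reduced χ²** — controls are scaled to a common total; per bin,
   χ²/(N−1) against the control mean; bins above the cutoff (default 3.5)
   are divided by their reduced χ² in every sample; bins with zero control
   mean are masked everywhere.

Match QC scores a sample's fraction profile against the control mean
(sum of squared deviations) and passes it within mean + 3 SD of the
controls' leave-one-out scores.

The chromosomal ratio divides target counts by counts on autosomes
excluding chromosomes 13/18/21 and X/Y, so a trisomy cannot deflate its own
normaliser. Z uses the control mean and SD (ddof = 1); the call is
one-sided (Z > 3, strictly) because only trisomies are in scope.

Cross-validation repeats 200 times: the test set is all cases plus an equal
number of randomly drawn controls, the remaining controls train μ and σ;
sensitivity, specificity and rank-statistic AUC (ties 0.5) are averaged,
with SDs and per-sample min/max Z retained. The minimum-fragment sweep
re-runs this after excluding samples below each threshold in
{1.0, 1.5, 2.0, 2.5, 3.0} million; a cell without qualifying cases is
undefined, not zero.

## Fetal fraction and sex (`fetal_fraction`)

A SNP is informative when the mother is homozygous and the fetus
heterozygous; the paternal allele's read fraction is then ff/2, so
ff = 2 × minor-allele fraction, aggregated by the **median** over
informative SNPs (robust to the occasional maternal-heterozygous site
misclassified by read-fraction gating; mean vs median is not dictated by
the estimator's definition). Without parental genotypes, informative sites
are gated by minor fraction in [0.005, 0.20]; truth genotypes are used
directly in simulation. Panels with mean depth < 50× fail QC; estimates
need ≥ 5 informative SNPs.

The chromosome-Y route interpolates the observed Y fragment share between a
female background and the share expected if all cfDNA were male
(an anchored linear stand-in for the published Y-count formulas, clamped to
[0, 1]). Sex calling: female iff SNP-ff > 4% and the Y-derived estimate is
≤ 1% (the 1% rule is read against the Y-derived fetal-fraction scale, not
the raw read share); male iff the Y estimate clears a 2% floor; otherwise
indeterminate.

## Panel design (`panel_design`)

Filters run in published order — excluded regions (X, Y, MT and the chr6
p-arm, implemented as a configurable interval with the whole short arm as
default), indels, non-biallelic sites, missing rs identifiers, MAF < 0.4,
exact Hardy–Weinberg p < 1e-5 (keep on equality) — with per-rule
first-failing counts. The HWE test is the exact conditional test (summing
heterozygote outcomes no more likely than observed), implemented with
log-factorials and validated against a rational-arithmetic enumeration
oracle. LD pruning slides a 50-SNP window in steps of 5, removing the later
SNP of any pair with r² ≥ 0.5 (squared Pearson correlation of 0/1/2
dosages; constant columns count as r² = 0). Primer screening rejects
homopolymer runs ≥ 4, ≥ 4 consecutive dinucleotide units, > 3 G/C in the
last 5 bases, or GC outside [0.4, 0.6]; no thermodynamics are computed.

## Clinical metrics (`clinical_metrics`)

Wilson score intervals use the normal quantile at full precision
(1.959964…); for k = n the lower bound reduces to n/(n+z²). PPV/NPV follow
Bayes' rule with the degenerate prevalences resolved by their limits, so a
test with 100% sensitivity reports NPV = 100.000% at any prevalence.

## Problem sizes and determinism

Unit tests run on a ~0.6 Mb genome; the acceptance checks use the full toy
scale: a 10,000-molecule error-free library for the round trip, 200
replicates for estimator calibration, and a cohort at 2.5 million fragments
per sample (the sample-QC operating point) for detection power — at that
depth the trisomy shift of ff/2 = 5% stands ~8 control SDs above the
euploid ratio. The reporting script uses the clinical study's cohort shape
(48 controls, 25 cases), which also fixes the cross-validation arithmetic
at 50 test / 23 training samples. Every stochastic step takes an explicit
`numpy.random.Generator` or seed; identical seeds give byte-identical
outputs.

## What the simulation does and does not show

Passing tests demonstrate that the analysis recovers planted truth exactly,
that estimators are calibrated under their stated sampling models, and that
the dosage algebra propagates to Z-scores with the expected power. The
simulation does **not** reproduce real-data failure modes: mapping bias and
mismapping (chrY background is exactly zero here), GC amplification bias in
library prep (the GC correction is exercised on synthetic strata), placental
mosaicism, maternal CNVs, or between-run batch effects. Sensitivity and
specificity measured on simulated cohorts characterise the statistical
machinery, not clinical performance. Sex-chromosome aneuploidies, multiple
gestations and maternal malignancy are out of scope.
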