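# smashnipt

Non-invasive prenatal testing (NIPT) detects fetal trisomies 13, 18 and 21
from the cell-free DNA (cfDNA) in a pregnant woman's plasma. Classic
shallow-WGS NIPT sequences one short cfDNA fragment per read, which wastes
most of a modern long (PE250) read: maternal cfDNA is ~166 bp, fetal ~143 bp.
This package implements an alternative protocol in silico and end-to-end:
cfDNA is enzymatically smashed to 40–50 bp pieces and randomly self-ligated
into long (>300 bp) *chimeric* molecules, so a single read pair carries
several independent genomic tags, multiplying the copy-number information per
read. A parallel targeted SNP amplicon assay estimates the fetal fraction.

`smashnipt` provides, as a library plus a thin CLI:

- **`simkit`** — generation of every input with known ground truth: a toy
  multi-chromosome reference with GC landscape, repeat and amplicon tracks, a
  SNP panel; maternal/fetal cfDNA mixtures with trisomy dosage; fragmentase +
  double-sided size selection; random self-ligation; PE250 reads; a truth SAM
  of split alignments; binomial SNP allele counts.
- **`smash_core`** — deconstruction of chimeric reads into per-tag fragments
  from primary + supplementary alignments, the published filters (MAPQ ≥ 60,
  repeat overlap, amplicon overlap, second-pass flags), FLASH-style pair
  merging, fragment statistics and sample QC (≥ 2,500,000 filtered fragments,
  fetal fraction ≥ 4%).
- **`aneuploidy`** — genome binning, variation reduction (peak → GC →
  reduced-χ² corrections), match QC, chromosomal ratios, Z-scores, repeated
  cross-validation, and a minimum-fragment threshold sweep.
- **`fetal_fraction`** — the doubled-paternal-allele estimator from
  informative SNPs, a chromosome-Y-based estimator, and the fetal sex call.
- **`panel_design`** — SNP panel selection (MAF ≥ 0.4, exact Hardy–Weinberg
  test, sliding-window LD pruning at r² < 0.5) and primer screening.
- **`clinical_metrics`** — Wilson score intervals and prevalence-indexed
  PPV/NPV.

## The statistic

For sample *s* the target-chromosome ratio is

    f_s = (reads on target chromosome) / (reads on reference autosomes)

where the denominator excludes chromosomes 13, 18, 21 and the sex
chromosomes. Against a euploid control set with mean μ and standard
deviation σ,

    Z_s = (f_s − μ) / σ ,   call trisomy iff Z_s > 3.

A fetal trisomy raises the target ratio by a factor ≈ (1 + ff/2) at fetal
fraction *ff*. The fetal fraction itself comes from informative SNPs (mother
homozygous, fetus heterozygous), where the paternal allele's read fraction is
ff/2, so ff = 2 × median paternal-allele fraction. Test performance is
summarised with Wilson 95% intervals and, for a population prevalence π,

    PPV = se·π / (se·π + (1−sp)(1−π)),   NPV = sp(1−π) / (sp(1−π) + (1−se)π).

## Worked example

```python
import numpy as np
from smashnipt import simkit, smash_core, io_cli, fetal_fraction

cfg = simkit.SimulationConfig(seed=7, n_cfdna_fragments=330_000,
                              fetal_fraction=0.10)
ref = simkit.make_reference(cfg)
rng = np.random.default_rng(cfg.seed)
frags = simkit.simulate_cfdna(ref, cfg, rng=rng)
pieces = simkit.fragmentase_and_select(frags, cfg, rng=rng)
molecules, truth = simkit.ligate_chimeras(pieces, cfg, rng=rng)
sam = simkit.emit_truth_sam(molecules, ref, cfg, "demo.sam", rng=rng)

sub = smash_core.extract_subreads(io_cli.stream_alignments(sam))
kept, stats = smash_core.filter_fragments(sub, ref.repeats, ref.amplicons)
fstat = smash_core.fragment_stats(kept, cfg.read_len,
                                  n_pairs=sub["read_id"].nunique())
print(f"molecules: {len(molecules)}  extracted tags: {len(sub)}  kept: {stats['kept']}")
print(f"mean tag length: {fstat['mean_fragment_len']:.1f} bp")
print(f"information ratio vs one 250 bp read: {fstat['info_content_ratio']}")
print(f"filtered tags per read pair: {fstat['fragments_per_pair_filtered']:.2f}")

counts = simkit.simulate_amplifet(ref, cfg, rng=rng)
est = fetal_fraction.estimate_ff(fetal_fraction.classify_informative(counts))
print(f"fetal fraction: {est.ff:.3f} from {est.n_informative} informative SNPs")
```

prints

```
molecules: 10896  extracted tags: 109652  kept: 38620
mean tag length: 43.8 bp
information ratio vs one 250 bp read: 5.7
filtered tags per read pair: 2.54
fetal fraction: 0.100 from 26 informative SNPs
```

The ~44 bp mean tag means each 250 bp read carries 5.7 tags' worth of
copy-number information, and after removing ambiguous, repeat-overlapping and
amplicon-overlapping tags each read pair still contributes ~2.5 usable tags.
The SNP estimator recovers the simulated 10% fetal fraction.

The same steps are available from the shell:

```bash
smashnipt simulate --out simdir --seed 7
smashnipt extract --sam simdir/truth.sam --repeats simdir/repeats.bed \
    --amplicons simdir/amplicons.bed --out fragments.tsv
smashnipt ff-estimate --counts simdir/allele_counts.tsv
smashnipt wilson --k 4 --n 4
smashnipt ppv-npv --se 0.9993 --sp 0.9914 --prevalence 0.005
smashnipt pipeline --out rundir --seed 7
```

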