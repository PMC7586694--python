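# oleapop

Population-genomic inference for olive (*Olea europaea*) domestication —
a tested, reusable re-implementation of the analysis pipeline used to ask
how cultivated olives diverged from wild oleasters: which sites survive
variant hard-filtering, how nucleotide diversity and differentiation are
distributed, where cultivar genomes carry introgressed wild alleles,
which genes show signatures of selection, and whether selective sweeps
fall inside introgressed segments more often than chance (adaptive
introgression).

The package is aimed at population geneticists who have a multi-sample
diploid VCF, GFF3 gene models, a reference FASTA and a sample manifest
(wild / eastern cultivars / admixed cultivars / outgroup), and want the
whole inference chain as composable, unit-tested Python functions. A
bundled synthetic-data generator emulates the study design — a wild
population, two cultivar populations shaped by a domestication
bottleneck, a single outgroup individual, codon-structured genes,
selective sweeps and GATK-style quality annotations — with full ground
truth, so every stage is testable without any sequencing data.

## What it computes

- **Hard and site filters** — retain records with MQ > 40, QD > 2,
  FS < 60, MQRankSum > −12.5, ReadPosRankSum > −8, SOR < 3, DP ≥ 10 and
  AD ≥ 5 in ≥ 80% of individuals (strict inequalities), then biallelic
  SNPs with MAF ≥ 0.008.
- **Codon-aware SNP classes** — intergenic / intronic / coding;
  synonymous vs nonsynonymous from the codon change (strand- and
  phase-aware), fourfold-degenerate and deleterious (start/stop-codon
  changes) flags; per-sample burdens and πN/πS with a fixed 1:3
  synonymous:nonsynonymous site-opportunity ratio:
  πN/πS = (Nn/Ns)·(1/3).
- **Diversity and neutrality** — windowed π (unbiased per-site
  2p(1−p)·n/(n−1), 20-kb tiles), Weir–Cockerham weighted
  F<sub>ST</sub> (ratio of summed variance components), per-gene
  Tajima's D on CDS sites (≥ 4 SNPs), outgroup-polarized derived SFS per
  functional class, and Mann–Whitney U contrasts between spectra.
- **Introgression** — Patterson's D = (ABBA−BABA)/(ABBA+BABA) with
  frequency-weighted site contributions (1−p₁)p₂p₃ and p₁(1−p₂)p₃,
  block-jackknife Z and Benjamini–Hochberg q across all tree-compatible
  trios; sliding windows of 5000 SNPs stepped by 1000; regions with
  D > 0.5 joined.
- **Selection** — McDonald–Kreitman tests with the neutrality index
  NI = (Pn/Ps)/(Fn/Fs) and Fisher exact p; a SweepFinder-style composite
  likelihood ratio scan (CLR every 5 kb, sweep strength α maximized per
  grid point, lineages escape with probability 1−e^(−αd)); top-0.5%
  outlier grid points collapsed into sweep regions.
- **Adaptive introgression** — total length of sweep regions fully
  contained in introgressed regions, against a permutation null that
  re-places the same region lengths at random (scaffold ∝ length, start
  uniform), p = #{resample ≥ observed}/reps.

## Worked example

```python
import numpy as np
import oleapop as op

params = op.CohortSimParams(seed=11, n_scaffolds=2, scaffold_length=100_000,
                            theta=0.006, differentiation=0.1,
                            bottleneck_factor=1.5, selection_proxy=0.6,
                            quality_fail_fraction=0.2,
                            sweep_spec=[("scaffold_1", 45_000, 1e-4)])
sim = op.simulate_cohort(params, out_dir="demo")
ds = op.load_dataset(sim.paths["vcf"], sim.paths["gff"],
                     sim.paths["fasta"], sim.paths["manifest"])
retained, report = op.apply_hard_filters(ds.genotypes)
snps = op.apply_site_filters(retained)
print(f"records: {report.n_input}, pass hard filters: {report.n_retained}, "
      f"biallelic MAF>=0.008: {snps.n_variants}")
ds.genotypes = snps
pi_w = np.nanmean(op.windowed_pi(ds, "wild")["pi"])
pi_c = np.nanmean(op.windowed_pi(ds, "cultivars_set1")["pi"])
print(f"pi (wild) = {pi_w:.2e}   pi (cultivars_set1) = {pi_c:.2e}")
print(f"weighted Fst wild~cultivars_set1 = "
      f"{op.weighted_fst(ds, 'wild', 'cultivars_set1'):.3f}")
tracks = op.clr_scan(ds, "cultivars_set1")
tr = tracks["scaffold_1"]
print(f"CLR argmax at {tr.grid_pos[np.nanargmax(tr.clr)]} bp "
      f"(true sweep center 45000), max CLR = {np.nanmax(tr.clr):.1f}")
```

prints

```
records: 5552, pass hard filters: 4442, biallelic MAF>=0.008: 3183
pi (wild) = 4.05e-03   pi (cultivars_set1) = 2.95e-03
weighted Fst wild~cultivars_set1 = 0.217
CLR argmax at 45000 bp (true sweep center 45000), max CLR = 18.0
```

Reading the output: 20% of simulated records carry a labelled quality
defect and exactly those are removed by the hard filters; the
bottlenecked cultivar population shows reduced diversity relative to the
wild one (π 3.0 vs 4.1 × 10⁻³) and moderate differentiation
(F<sub>ST</sub> ≈ 0.22); the sweep scan recovers the simulated sweep at
the exact grid point.

A command-line layer mirrors the library
(`oleapop simulate|load|filter|classify|diversity|fst|tajima|sfs|dstat|dinvestigate|mk|sweep|overlap`);
see `oleapop --help`.

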