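# Methods

This note documents the models implemented in oleapop, the synthetic
data they are validated on, the numerical choices made where the design
was open, and what the tests do and do not demonstrate.

## Variant retention

Hard filtering follows the GATK-style battery with strict inequalities:
a record is kept iff MQ > 40 ∧ QD > 2 ∧ FS < 60 ∧ MQRankSum > −12.5 ∧
ReadPosRankSum > −8 ∧ SOR < 3, DP ≥ 10 in ≥ 80% of individuals and
AD ≥ 5 in ≥ 80% of individuals; records at a threshold exactly are
rejected. Sites with any missing genotype or a spanning-deletion allele
are removed first and reported separately. Three decisions the tools'
documentation leaves open:

- **Missing INFO annotations** (the rank sums are emitted only for sites
  with a heterozygote) pass their rule, matching common GATK practice;
  they are tallied separately in the filter report.
- **AD** is interpreted as depth supporting the sample's *called*
  alleles (hom: that allele's depth; het: the minimum of both). Reading
  it as ALT-supporting depth would fail nearly every low-frequency site
  — hom-REF samples always have ALT depth 0 — making genome-scale SNP
  retention impossible, so that reading cannot be what the rule means.
- The DP/AD **80% denominator** is all manifest samples, not just
  non-missing ones ("in at least 80% of individuals").

The MAF filter (≥ 0.008, biallelic only) computes frequency over called
alleles, excluding missing genotypes from the denominator. Filtering is
idempotent and order-stable; a property test re-evaluates the full
predicate per record under random thresholds.

## Site classification

Codon effects use the standard nuclear genetic code (stops TAA/TAG/TGA),
strand- and phase-aware. A SNP is synonymous iff the amino acid is
unchanged; fourfold when all four bases at its codon position encode the
same amino acid; deleterious when it destroys the initiator ATG,
destroys the terminal stop, or creates a premature stop. Variants are
classified one at a time against the reference codon — two SNPs in one
codon are not resolved jointly (a limitation shared with SNP-wise
pipelines). πN/πS uses a fixed 1:3 synonymous:nonsynonymous
site-opportunity split of the coding length L: πN = Nn/(0.75 L),
πS = Ns/(0.25 L); the ratio (Nn/Ns)/3 is independent of L (verified
algebraically and by test) and is reported as missing, never infinite,
when Ns = 0. Per-sample ratios are available for homozygous-only,
heterozygous-only and all SNPs (default).

Gene presence from read depth honors the two quoted rules literally and
uses different denominators on purpose: *present* = depth > 5 over ≥ 90%
of the **coding** region; *candidate unique* = NOT depth > 20 over ≥ 50%
of the **gene span**; *stringent unique* = NOT depth > 5 over ≥ 50% of
the span.

## Diversity and neutrality statistics

π is the unbiased per-site estimator 2p(1−p)·n/(n−1) over called
chromosomes (pairwise-complete handling of missing data), summed per
20-kb tile anchored at position 1 and divided by the tile's true bp
length (the trailing partial window uses its real length). Weighted
F<sub>ST</sub> is Weir–Cockerham (1984) for two diploid populations,
aggregated as the ratio of summed variance components across sites —
never a mean of per-site ratios. Tajima's D uses the standard
a₁…e₂ constants with n = 2 × samples (exposed as a parameter) over CDS
sites with complete calls, skipping genes with fewer than 4 segregating
sites. The derived SFS is polarized by a homozygous outgroup call; sites
with a heterozygous, missing or discordant outgroup are excluded and
counted. SFS contrasts use the Mann–Whitney U test on the per-site
derived counts implied by the histograms: exact (a tie-aware dynamic
program over histogram bins, equivalent to full permutation enumeration)
when both classes have ≤ 20 sites, otherwise the tie-corrected normal
approximation with continuity correction.

## Introgression

Patterson's D uses frequency-weighted contributions per polarizable site
— ABBA: (1−p₁)p₂p₃, BABA: p₁(1−p₂)p₃ — which reduces to pattern counting
for single homozygous individuals. Sites must be polarizable and fully
called in all trio members. Standard errors come from a delete-one block
jackknife over 20 contiguous equal-SNP blocks (a parameter), Z = D/SE,
two-sided normal p, Benjamini–Hochberg q across the trio set. Trios are
enumerated from a rooted guide tree: for each 3-subset the pair with the
deeper MRCA is {P1, P2}; polytomies are emitted flagged unresolved.
Windowed D slides over runs of consecutive usable SNPs (5000-SNP
windows, 1000-SNP steps by default; ordinal indexing, full windows
only), and regions are the union of window spans with D strictly above
0.5, labelled with the mean window D.

## Selection scans

The MK test counts, for coding sites, polymorphisms within the focal
population and fixed differences (the two populations fixed for
different alleles, no sharing), split synonymous/nonsynonymous.
NI = (Pn/Ps)/(Fn/Fs) is defined only when Ps, Fn, Fs > 0; Fisher exact
two-sided p per table (p = 1 for zero-margin tables), BH across genes.

The sweep scan models, at each grid point (every 5 kb;
⌊length/5000⌋ points per scaffold), a completed sweep of strength α: a
lineage at distance d escapes by recombination with probability
p_e = 1 − e^(−αd); conditional on the site's pre-sweep derived frequency
x (drawn from the genome-wide background SFS) and the sweeping
haplotype's allele B ~ Bernoulli(x), the n sampled lineages are
independent with derived probability p_e·x + (1−p_e)·B, so the derived
count is a binomial mixture, conditioned on polymorphism because only
SNPs are observed. α is maximized over 41 log-spaced values in
[10⁻⁶, 10²] per bp (wide enough that the largest α reproduces the
background model, so CLR = 2·(max log L_sweep − log L_background) is
floored at 0 without bias). Outliers are the top 0.5% of grid points by
CLR — rank-equivalent to any monotone tail probability of the CLR;
ranking by a χ²₁ tail is provided and tested to give identical regions —
with ties at the cutoff all included and CLR = 0 points (exact
background fits) never outliers; points closer than 10 bp collapse. The
per-site mixture likelihood is verified against brute-force enumeration
over escape configurations for n ≤ 6 at 10⁻¹⁰.

## Sweep × introgression overlap

The observed statistic is the total length of sweep regions wholly
contained in an introgressed region (the "100% overlap" reading); an
intersection-length mode exists for sensitivity analysis, and the same
statistic is applied to observed and resampled sets for symmetry. Each
of the `reps` (default 1000) resamples preserves every sweep-region
length exactly ("similar sizes" taken at its strongest), placing each
region independently on a scaffold drawn ∝ length among scaffolds it
fits, start uniform; collisions are allowed, overhangs are not.
p = #{resample ≥ observed}/reps, floored at 1/reps. An optional ±10%
length jitter relaxes the exact-length reading. Calibration is checked
by generating sweeps under the same placement law: the test rejects at
α = 0.05 in 3–8% of 200 null configurations.

## The synthetic cohort

The generator is frequency-based rather than coalescent: ancestral
derived frequencies follow the neutral 1/i spectrum, populations deviate
by Balding–Nichols Beta draws at the chosen F<sub>ST</sub>, diploid
dosages are Binomial(2, p). This keeps every expectation in closed form
(the quartet simulator exposes its exact site-pattern multinomial; the
class-SFS sampler its exact induced spectrum) at the cost of realism: no
linkage disequilibrium, no recombination maps, one mutation per site.
Specific components:

- **Bottleneck** (cultivars): extra drift via a second Beta draw with
  F_b = 1 − 1/b for bottleneck factor b ≥ 1. This loses rare alleles or
  drifts them upward, which both lowers diversity and shifts the
  segregating-site SFS toward intermediate frequencies — the classic
  domestication signature. The admixed cultivar set mixes wild and
  eastern-cultivar frequencies (30% wild by default).
- **Selection proxy** s ∈ (0,1] multiplies nonsynonymous derived
  frequencies; πN/πS is monotone in s by construction and by test.
- **Sweeps** use the same escape model as the scanner (shared escape
  probability), so sweep-recovery tests are deliberately
  self-consistency checks of the inference machinery, not evidence that
  the scanner detects sweeps generated by a different process.
- **Quality fields**: passing records draw comfortably inside all
  thresholds; a labelled fraction each violates exactly one named rule,
  with the first three failures pinned exactly at MQ = 40, QD = 2,
  FS = 60 to exercise boundary semantics.
- Genes are non-overlapping, ATG…stop, no internal stops, mixed strands,
  with exon/intron structure; coding variants are classified at
  generation time with the same genetic code the classifier uses, and a
  file-level round trip (FASTA+GFF3+VCF → loader → classifier) must
  reproduce the truth classes exactly.
- Defaults are chosen to emulate the study system at desk scale: 10
  wild, 10 + 10 cultivar and 1 outgroup samples; θ = 0.004/bp giving
  π ≈ 3.5 × 10⁻³ (olive-scale diversity); generation time 20 y and
  μ = 7.77 × 10⁻⁹ carried as annotation metadata. Identical seeds give
  bit-identical files.

The neutral-SFS goodness-of-fit target is the generator's *induced*
spectrum (1/i frequencies resampled binomially, conditioned on
segregating), not raw 1/i: binomial sampling visibly smooths the
spectrum at 10⁴ sites, and testing against the wrong null would reject a
correct implementation.

What passing tests show: the statistics are algebraically correct
(oracle equivalence at 10⁻¹⁰), calibrated under their own null models,
and powerful against the generator's alternatives. What they do not
show: performance under linkage, demographic misspecification, or real
sequencing artifacts beyond the simulated quality fields.

## Problem sizes

Simulation-based checks run at desk scale chosen once: two 100-kb
scaffolds (~1200 SNPs each at θ = 0.006 for sweep tests), 10⁴ sites per
quartet replicate, 20–50 seeds per calibration or power check, 200 null
configurations × 500 reps for the permutation calibration. The sweep
scan on this grid evaluates 20 grid points × 41 α values per scaffold in
a fully vectorized log-likelihood (about 2 s per scaffold).
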