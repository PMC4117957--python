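# Methods

## Scope and model

The package reconstructs a comparative population-genomics workflow
over two marker systems: a fixed SNP-chip panel (60K-style, subject to
ascertainment bias and sparse coverage) and per-individual
whole-genome variant calls at moderate (~10x) depth. All analyses are
diploid, autosomal and biallelic; multi-allelic sites and INDELs are
removed (or, for INDELs, flagged and excluded from SNP-only stages) at
ingest. Genotypes are coded 0/1/2 as alternate-allele counts with −1
for missing. Internally every position is 0-based and every interval
half-open `[start, end)`; VCF/TSV writers emit 1-based SNP positions,
BED writers emit 0-based half-open intervals.

### Estimators

* **Ho** — per locus, heterozygotes over non-missing diploids; loci
  with no data in a population are excluded rather than counted as 0.
* **He** — unbiased gene diversity `(2n/(2n−1))(1 − p̂² − q̂²)` with n
  the non-missing diploid count at the locus, averaged over
  polymorphic and monomorphic loci alike. The small-sample correction
  matches standard genotype-analysis software; at the sample sizes
  this workflow targets (13–46 per breed) it changes He by <4 %.
* **F** — method-of-moments excess homozygosity
  `(O_hom − E_hom)/(L − E_hom)` with `E_hom = Σ 1 − 2p̂q̂·2N/(2N−1)`.
  Allele frequencies come from the **total** sample, not the
  individual's breed; this makes F absorb between-breed divergence
  (a Wahlund-type inflation) exactly as when F is computed across a
  combined dataset before averaging per breed. Loci where the
  individual is untyped are excluded; the estimate is NaN when
  `L = E_hom`.
* **h_NGS** — heterozygous SNPs per 50-kb bin over callable sites per
  bin. "Callable" means per-base depth in `[7, 2·mean]`; the ceiling
  uses the individual's genome-wide mean depth, "approximately 2x"
  read as exactly 2x. Bins with fewer than 20 % callable sites are
  dropped (the threshold is a config, not a published value). The
  correction for the number of sites per bin is implemented as the
  ratio h = het/callable (a regression-style correction would be an
  alternative reading; the ratio is the plain one).
* **θ (F_ST)** — Weir & Cockerham (1984) variance components
  `a, b, c` from per-population sizes, allele frequencies and observed
  heterozygote fractions; per-locus θ = a/(a+b+c), multi-locus
  F_ST = Σa/Σ(a+b+c). Negative per-locus values are retained —
  clamping would bias the ratio — and θ = 1 holds exactly iff the two
  groups are fixed for different alleles. Loci with fewer than two
  informative populations, or with n̄ ≤ 1, are NaN and skipped by the
  multi-locus sum. The test suite validates the implementation against
  an independently coded ANOVA mean-squares route (MSG/MSI/MSP from
  raw genotypes) to 1e−12. Note one estimator subtlety: duplicating
  the *same* individuals into two "populations" gives a small O(1/n)
  negative estimate, not exactly 0, because the realized
  between-population variance is zero while its finite-sample
  correction is not.

### ROH callers

*Chip rule* — maximal marker segments with ≥20 homozygous SNPs, ≤1
heterozygous call (a single global budget, not per-window), span
≥10 kb, no gap >1 Mb, density ≥1 SNP/Mb. Endpoints are the outermost
homozygous markers; missing calls are transparent (neither support nor
break). When two heterozygotes split a long run, the maximal segment
on either side is reported even though the two overlap between the
hets; genome-fraction summaries count overlapping bases once. With
default parameters the density bound is implied by the gap bound
(n SNPs with all gaps ≤1 Mb span ≤(n−1) Mb); it is still checked so
non-default configurations behave as documented.

*Sequence rule* — non-overlapping 100-kb bins (the tiling reading of a
"100-kb sliding window"; the window step is a config, not assumed),
counting heterozygous SNPs per bin by default — homozygous-alternate
calls are not evidence against autozygosity (`density_counts`
switches to all variant sites). Chains of consecutive bins at ≤0.25x
the genomic bin average become a ROH when ≥10 bins long and the chain
mean stays below the genomic average (the second condition is implied
by the first but kept explicit, matching the stated rule). Bins
failing the callability floor break chains — the conservative choice;
runs separated by a single non-qualifying bin are not merged.

### Screen, polarization, overlap test

The fixed-difference screen applies the genotype rules directly
(every typed commercial pig homozygous for one allele with ≤3 of 8
missing; both local animals homozygous for the other; breeds with one
sequenced animal or one missing call contribute nothing) rather than
thresholding θ, because θ's missing-data behaviour is subtler than the
explicit rules; θ = 1 is kept as a cross-check on every emitted
record. One consequence worth knowing: the screen is *not* globally
monotone in missingness — masking a heterozygous commercial call can
turn a rejected locus into an accepted one, since the remaining typed
pigs may be uniformly homozygous. Monotonicity does hold for
missingness in the local animals, and is tested there.

Polarization takes the outgroup's homozygous allele as ancestral when
it is one of the two segregating alleles; heterozygous, missing or
third-allele outgroup calls leave the record unpolarized.

The overlap test resamples SNP identities from the genome-wide
non-synonymous pool (conditioning on non-synonymous ascertainment),
without replacement, k per draw — not by shuffling QTL intervals.
The empirical p uses the add-one rule so p ≥ 1/(n_perm+1). Because
draws are exchangeable, the null overlap count is hypergeometric in
the number of pool SNPs covered by the category; `exact=True` reports
that tail directly and equals exhaustive enumeration. Per-category
p-values are raw, as is conventional for this kind of exploratory
overlap report; a Benjamini–Hochberg column is available but off by
default.

## The synthetic-data generator

The generator emulates the study design, not the biology of any real
breed:

* **Genotypes** — per locus, with probability f the individual is
  autozygous and receives a homozygote by allele frequency, else a
  Hardy–Weinberg draw; this equals P(het) = 2pq(1−f),
  P(hom-alt) = q² + fpq exactly. Base frequencies are uniform on
  [0.05, 0.95] per locus — a free parameter, not a claim about any
  real site-frequency spectrum. Breed differentiation comes from
  Balding–Nichols beta drift around the shared base frequencies
  (drift c gives Var(p′) = c·p(1−p)), so loci span the full FST range.
* **ROH** exist by implantation (intervals forced homozygous with
  alleles drawn from the base frequencies), not by pedigree; there is
  no coalescent, recombination, linkage or mutation model.
* **Sequencing** — per-site depth is Poisson around the target mean
  (default 10x); genotypes are masked outside the emission window
  [5, 2·mean]. The callability track stores callable-site counts per
  10-kb tile: for i.i.d. per-base Poisson depths, the count of
  callable bases in a tile is exactly Binomial(tile, q), so tiles are
  drawn binomially rather than simulating 10⁸ bases. Variant-site
  depths and the track are drawn independently — a deliberate
  approximation; the overlap between the two processes is negligible
  at the densities used. 2 % of records get quality below the QC
  floor, 3 % are INDELs, 2 % of SNPs are labelled non-synonymous with
  damage labels drawn 60/25/15 benign/possibly/probably damaging.
* **Fixed differences** — implanted per local breed on non-synonymous
  loci (commercial forced hom-ref, the breed's two animals hom-alt,
  depth and quality pinned callable), with 64 % of implants putting
  the derived allele on the local side. Decoy loci with one local
  animal knocked out, and loci with four commercial dropouts, exercise
  the exclusion rules. The ground-truth table is produced by a
  separate direct pass over the emitted genotype/missingness state
  (with quality <20 counted as missing, mirroring variant QC), so
  *accidental* fixed differences arising from the frequency draws are
  part of the truth, not just the implants.
* **QTLs** — intervals uniform on the genome except a fraction
  `enrichment` anchored to cover chosen SNPs; categories are
  independent sets. The outgroup is homozygous ancestral with 2 % het
  and 5 % missing noise.

What the generator does **not** emulate — linkage disequilibrium,
ascertainment bias of the chip panel (chip and sequence loci are drawn
from the same frequency distribution), mapping artefacts, error modes
correlated along the genome, and realistic site-frequency spectra.
Passing tests therefore demonstrate that the *rules and estimators*
are implemented correctly and recover planted structure; they do not
certify behaviour on real data with LD or ascertainment bias.

## Problem sizes and numerical choices

The default study runs on a 2 x 50 Mb genome: 2,400 chip markers
(24/Mb, matching 60K over a 2.5-Gb genome) and 100,000 sequence SNPs
(1/kb), 12 individuals, simulating in ~4 s and running end to end in
~15 s. On this scaled genome the sequence ROH caller is run at 10-kb
bins (x10 consecutive), scaling the bin with the ~25x genome
reduction; the library default stays at the full-scale 100-kb value.
Consequently absolute h_NGS values are ~2.5e−4 rather than the ~1e−3
of real pig genomes — SNP density on the toy genome is lower — while
every comparative statement (rankings, correlations, detection
contrasts) is scale-free.

Estimator-recovery checks use 20k loci (F within ±0.05 of simulated
f) and 40k sequence SNPs per individual. Permutation calibration uses
k = 400 draws from a pool of 10,000 with a category covering half the
genome: the overlap-count distribution then has sd ≈ 10, so its
discreteness is negligible against the Kolmogorov–Smirnov critical
distance at 200 replicates — at much smaller k the stepped p-value
distribution fails a continuous-uniform KS test for reasons unrelated
to calibration. Power checks use k = 20 and 80 % interval enrichment.

Tie-breaking and degeneracies: UPGMA leaves are sorted
lexicographically before clustering so ties resolve deterministically;
FST matrices are symmetrized and clamped at 0 for tree building only;
monomorphic loci contribute nothing to multi-locus FST; undefined
quantities (zero callable bins, constant correlation inputs,
degenerate θ) are reported as NaN rather than raised, except where an
input is unusable (no callable bins at all, zero genomic SNP average),
which raises.

All randomness flows from a single integer seed through
`numpy.random.Generator`; reruns are byte-identical, which the test
suite verifies at file level.

## Known limitations

* The chip ROH caller over-extends segment boundaries to the nearest
  heterozygous marker and calls chance-homozygosity runs at high
  background inbreeding; whether chip coverage under- or over-states
  the true ROH fraction therefore depends on how much of the ROH mass
  is short. With short-run-dominated landscapes (the realistic case)
  chip underestimates, and the comparison report measures exactly
  this contrast.
* Commercial lines are pooled as one population throughout (simple
  pooling of the eight animals); weighted pooling is not implemented.
* The screen requires exactly-two sequenced animals per local breed;
  breeds with one animal are excluded entirely (the conservative
  reading of the exclusion rule).
* No F_ROH estimator, no IBD sharing, no haplotypes, no CNVs, no
  sliding-window FST scans, and no significance testing of θ.
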