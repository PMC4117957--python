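# pigpop

Comparative population genomics of low-input (local) pig breeds against
commercial elite lines, from two marker systems at once: fixed-panel
SNP-chip genotypes (60K-style) and whole-genome resequencing variant
calls (~10x). The package implements the full analysis chain —
diversity and inbreeding estimation, runs of homozygosity (ROH) from
both marker systems, Weir–Cockerham F<sub>ST</sub> with a
fixed-difference screen over non-synonymous SNPs, outgroup
polarization of alleles, and a permutation test of SNP–QTL overlap —
together with a synthetic-data generator that provides ground truth
for every stage, so the whole pipeline is testable end to end without
any external download.

It is written for population geneticists who want either the pieces
(library functions over `GenotypeMatrix` / `VariantTable` containers)
or the whole workflow (numbered analysis scripts, or the `pigpop` CLI).

## The statistics at the core

**Diversity and inbreeding (chip).** Observed heterozygosity Ho is the
mean over loci of the heterozygote fraction among non-missing calls;
expected heterozygosity is the unbiased gene diversity
He = (2n/(2n−1))(1 − p̂² − q̂²) averaged over loci. The per-individual
inbreeding coefficient is the method-of-moments excess homozygosity

    F = (O_hom − E_hom) / (L − E_hom),   E_hom = Σ_loci [1 − 2p̂q̂·2N/(2N−1)],

computed against total-sample allele frequencies over the individual's
L typed loci; negative F flags recent outcrossing.

**Sequence heterozygosity.** h<sub>NGS</sub> is the number of
heterozygous SNPs per 50-kb bin divided by the callable sites in the
bin (per-base depth within [7x, 2x the genome-wide mean]); bins with
under 20 % callable sites are dropped, individuals average their bins,
breeds average their individuals.

**ROH, two ways.** The chip caller reports maximal marker segments
that are ≥10 kb long, contain ≥20 homozygous SNPs, tolerate one
heterozygous call, and have no inter-marker gap above 1 Mb (≥1 SNP/Mb
density). The sequence caller tiles the genome into 100-kb bins and
extracts chains of ≥10 consecutive bins whose heterozygous-SNP count
is ≤0.25x the genomic bin average.

**Differentiation.** Per-locus Weir–Cockerham (1984) θ = a/(a+b+c)
from variance components; multi-locus F<sub>ST</sub> is the
ratio-of-sums Σa/Σ(a+b+c); breed trees by UPGMA (default) or
neighbour joining on the pairwise matrix, serialized as Newick.

**Fixed-difference screen.** A non-synonymous SNP is retained for a
local breed when every typed commercial pig (missing in ≤3 of 8) is
homozygous for one allele and both of the breed's sequenced animals
are homozygous for the other — exactly the genotype configuration with
θ = 1. Records are polarized ancestral/derived against an outgroup
(warthog-style) genome.

**QTL overlap.** For each QTL category, the observed number of
screened SNPs inside ≥1 interval is compared with 1,000 resamples of
the same number of SNPs drawn without replacement from the genome-wide
non-synonymous pool; p = (1 + #{null ≥ observed})/(1 + 1,000).

## Worked example

The analysis scripts regenerate everything under `results/`:

```bash
python analysis/01_simulate_cohort.py   # write the synthetic cohort + ground truth
python analysis/02_diversity.py
python analysis/03_roh.py
python analysis/04_differentiation.py
python analysis/05_fixed_screen.py
python analysis/06_qtl_overlap.py
```

The cohort is a 2 x 50 Mb toy genome carrying 60K-density chip markers
and 1 sequence SNP per kb for 12 pigs: 8 commercial (simulated
inbreeding f = 0.15) and two local breeds of two sequenced animals
each (f = 0.30 and 0.50), with ROH segments and commercial-vs-local
fixed differences implanted at known positions. Selected output:

```
concordance (Pearson):
    pair      level       r      p  n
Ho~h_NGS population  0.9999 0.0074  3
 F~h_NGS individual -0.9897 0.0000 12

means: seq Jaccard 0.992; short-ROH detection seq 1.00 vs chip 0.22

screen: 47 records, 42 SNPs, 24 genes; per breed {'LocalA': 23, 'LocalB': 24}
matches ground truth exactly: True (47/47 shared, 0 mismatched)
polarity (n=36 polarized): derived allele fixed in local breeds 66.7% vs commercial 33.3%

    category  observed  k  null_mean      p  n_perm
    exterior        29 42      9.939 0.0010    1000
meat_quality        12 42     11.331 0.4486    1000
  production        23 42     11.952 0.0010    1000
    vertebra        10 42      9.528 0.5015    1000
```

Reading this: the two marker systems agree (individual-level
F vs h<sub>NGS</sub> correlation −0.99); the sequence ROH caller
recovers the implanted segments at bp Jaccard 0.99 while the chip
caller finds only 22 % of the short (<200 kb) stratum; the screen
reproduces the generator's fixed-difference truth table exactly with
the designed ~2:1 derived-in-local polarity; and the permutation test
flags exactly the two QTL categories that were enriched by
construction (p = 0.001) while leaving the null categories
non-significant.

The same workflow is available as a CLI (`pigpop demo --seed 7`, or
per-stage subcommands `io-qc`, `diversity`, `het-bins`, `roh-chip`,
`roh-seq`, `fst`, `screen`, `qtl-overlap`, `run`).

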