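# hybridtrace

Genome-of-origin attribution of transcripts in cell-fusion hybrid cells.

## The problem

When a human embryonic fibroblast (HEF) is fused with a fetal-liver
CD34+ hematopoietic progenitor (hFL), the resulting tetraploid hybrid
carries two copies of each donor genome. Expression profiling can show
that the hybrid behaves like an erythroid cell, but it cannot by itself
distinguish two hypotheses: the fibroblast genome was *transcriptionally
reprogrammed*, or it is merely retained as *silent cargo* while the hFL
genome does all the transcribing. Short reads from the hybrid
transcriptome settle the question at **discriminating SNPs** — exonic
sites where the donor genomes are either homozygous for different
alleles, or heterozygous in exactly one donor — because there the allele
a read carries identifies the genome that produced it.

For a balanced tetraploid (2+2 copies, equal per-copy expression) the
theoretical read shares are:

* homozygous-different site: each donor's allele at **50%/50%**;
* single-heterozygous site: the shared (3-copy) allele at **75%** and
  the heterozygous donor's unique (1-copy) allele at **25%**.

Silent cargo predicts instead that HEF-identifying alleles vanish from
the transcriptome. `hybridtrace` implements the whole desk-scale
analysis — hybrid-read simulation with ground truth, UP1/UP2 anchor
(BstU1) trimming, unique ungapped alignment, pileup consensus calling
with 1st/2nd-best base frequencies, List A × List B SNP selection with
the read-count (>5) and 4-fold differential-expression filters, and
copy-number-weighted attribution with a binomial regime test — for
scientists who want to study or teach this attribution paradigm with
fully controlled synthetic data.

## The statistics at the core

At a verified SNP with allele counts `n_a`, per-site fractions are
summarized per category as mean ± SD (SD across SNPs) against the
theoretical expectation. Three attribution conventions are implemented
for single-heterozygous sites (shared allele count `s`, unique count
`u`):

* **allele_ratio** — majority share `s/(s+u)`, expectation 3/4;
* **copy_proportional** — shared reads split 2/3 to the homozygous and
  1/3 to the heterozygous donor (exact thirds conserve reads; the
  literal 0.66/0.33 coefficient variant is available), unique reads
  wholly to the heterozygous donor;
* **unique_allele** — `s` wholly to the homozygous, `u` wholly to the
  heterozygous donor, reproducing the 25%/75% expectation.

Homozygous-different sites attribute each allele wholly (coefficient 1)
to its donor. The regime test applies a two-sided binomial test per SNP
against the copy-proportional expectation (Bonferroni-corrected) and
reports `reprogrammed`, `cargo`, `ambiguous` or `inconclusive`.
Expression utilities provide quantile normalization (average-rank ties),
`log2((a+c)/(b+c))` fold changes and the Pearson product-moment
correlation computed from standard scores.

## Worked example

The packaged twelve-row verified-SNP table (genomic positions, donor
array genotypes including one missing `N/A` cell, `count\depth`
frequency strings, per-gene log2 expression differences) runs through
selection and attribution directly:

```python
from hybridtrace.fixtures import (table1_genotype_table, table1_expression_log2fc,
                                  table1_consensus_table)
from hybridtrace.select import (build_list_a, build_list_b, cross_lists,
                                de_filter, snps_from_frame)
from hybridtrace.attribution import AttributionConfig, attribute_reads

genotypes = table1_genotype_table()
snps, cascade = build_list_a(genotypes)
print("filter cascade:", cascade)
verified = cross_lists(snps, build_list_b(table1_consensus_table()))
print("verified SNPs:", len(verified))
up, down, summary = de_filter(genotypes, table1_expression_log2fc())
print("DE split:", summary)

rec = attribute_reads(snps_from_frame(verified)[0],
                      {"C": 53, "G": 28}, AttributionConfig.literal())
print(f"weighted reads  HEF19: {rec.weighted_donor1:.2f}   hFL24: {rec.weighted_donor2:.2f}")
```

prints

```
filter cascade: {'input': 12, 'exonic': 12, 'discriminating': 11}
verified SNPs: 11
DE split: {'up_snps': 11, 'up_genes': 7, 'down_snps': 1, 'down_genes': 1}
weighted reads  HEF19: 62.24   hFL24: 18.48
```

Eleven of the twelve sites are usable discriminators (the `N/A` row
drops out), all pass the strict read-count rule (smallest depth 7 > 5),
and the 4-fold expression filter splits them into 11 up-regulated SNPs
in 7 genes plus 1 down-regulated SNP in 1 gene (ACTG1). The last line is
the literal-coefficient weighting of the first site (HEF19 heterozygous
CG, hFL24 homozygous GG, counts C=53 G=28): the heterozygous donor
receives 53 + 0.33·28 = 62.24 weighted reads and the homozygous donor
0.66·28 = 18.48.

End-to-end simulated runs are one command:

```sh
hybridtrace run --outdir out --seed 2          # simulate → trim → call → select → attribute
hybridtrace fixtures --outdir fixtures         # write the packaged fixture set
```

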