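# Methods

## The hybrid model

A fusion hybrid is modelled as a tetraploid cell carrying two haplotype
copies of each donor genome (`donor1` = HEF-like fibroblast, `donor2` =
hFL-like erythroid progenitor); an octaploid variant carries four copies
per donor with equal per-copy expression and therefore the same expected
allele ratios. Donor genomes are identical to a shared transcript
reference except at listed SNP sites, each realized in one of five
zygosity configurations: homozygous-both-different, heterozygous in
exactly one donor (either donor), heterozygous in both (same pair), or
identical homozygous. Sites are biallelic and the reference base is one
of the two alleles at every discriminating site, matching how
array-genotyped SNPs present; identical-homozygous sites may be
homozygous for the non-reference allele so that the transcriptome SNP
list (List B) also sees non-discriminating variation. A heterozygous
genotype places one allele on each copy, so a single-het site has a 3:1
copy ratio between the shared and unique alleles.

Transcription is governed by the erythroid (hFL-like) expression
profile: under the **reprogrammed** scenario all four copies of a gene
express at the hFL-like level; under the **silent-cargo** scenario the
donor1 copies are additionally multiplied by a silencing factor
(default 0 = fully silent — the degenerate negative control). An
`expression_skew` multiplier on the donor1 copies lets simulations probe
unbalanced hybrids; at homozygous-different sites a skew *s* predicts a
donor1 read share of *s/(1+s)*.

## Read simulation

Reads are single-end, 36 nt by default (the short-read length typical
of the instrument generation this analysis targets; configurable), with
uniform start positions within each transcript — no fragment-length or
positional-bias model. Read counts per (transcript, copy) are Poisson
with mean `coverage x expression / mean(expression) x copy factor`;
`coverage_for_depth` converts a target per-site depth into this per-copy
coverage (depth ≈ coverage x copies x read_length / (L - read_length + 1)).
Errors are uniform substitutions at a per-base rate (default 0.01); no
indels, since the attribution statistics are substitution-based. An
optional contamination fraction of reads carries a verbatim UP1/UP2
anchor + poly-T prefix. Every read is recorded in a truth table (origin
donor, copy, offset), which the alignment and attribution tests check
against. Expression baselines are log-normal (median 100 arbitrary
units, σ = 0.25 on the log scale — narrow enough that baseline noise
never crosses the 4-fold differential-expression mark); designated
fold-change genes split a shared baseline symmetrically so the linear
ratio is exactly 2^log2FC.

What the generator does *not* emulate: splicing isoforms, mapping bias
from paralogs or repetitive exons, PCR amplification bias,
quality-score structure, and real array noise. Passing tests therefore
demonstrate the correctness of the pipeline's logic and its statistical
behaviour under the stated model, not robustness to those real-data
artifacts.

## Library cleanup

The cDNA protocol brackets inserts with anchor primers
(`UP1 = ATATGGATCCGGCGCGCCGTCGACCGCG + T×24`, `UP2 =
ATATCTCGAGGGCGCGCCGGATCCCGCG + T×24`), each containing a BstU1 site.
In-silico digestion cuts `CG^CG` (blunt), scanning left to right and
resuming at each cut so chained sites are fully digested; fragment
concatenation always reproduces the input. Trimming removes a read
prefix matching an anchor within 1 mismatch (default) plus every
following T — the primer's poly-T tract, not transcript poly-A, which is
left alone — looping until no anchor prefix remains (idempotence).
Reads shorter than 20 nt afterwards are dropped and counted. With 36 nt
reads an anchor-bearing read is pure primer and is dropped entirely,
which is the intended effect of the cleanup.

## Alignment and consensus calling

The aligner is an exact 12-mer seed index plus ungapped extension over
both strands; a read is reported only if exactly one location matches
within 2 mismatches (defaults), and multi-hits/ties are discarded.
Seeds are taken every k bases plus one flush with the read end, so
detection is exhaustive for ≤ floor(len/k) − 1 mismatches — at the
36/12/2 defaults, always. Reads aligning to the reverse strand
contribute reverse-complemented bases to the pileup; N bases are
excluded from depth.

The consensus caller ranks bases by count with alphabetical tie-break
and calls first/second-best heterozygous iff the second-best count is at
least `max(min_minor_reads=2, minor_fraction=0.2 x depth)`. This is a
frequency rule, not a Bayesian quality-model re-sequencing caller; it is
deliberately simple, validated against exhaustive enumeration of every
pileup of depth ≤ 6 and against error-free simulations. Consequence: a
true heterozygote whose minor allele falls below 20% of depth (possible
by sampling noise at low depth, and present in some printed worked-table
rows) is called homozygous; the thresholds are configurable.
Frequencies are rendered as `count\depth` strings to match the
worked-table dialect exactly.

## SNP selection

Genotype pairs classify as HOM_HOM_DIFF (both homozygous, different),
HET_ONE (exactly one heterozygous, homozygous allele within the het
pair) or non-discriminating (identical, both-het, missing `N/A`, or
more than two distinct alleles — impossible for a biallelic array SNP
and treated as unusable). List A applies exonic → discriminating →
(optional) differential-expression filters in order, logging per-stage
counts; List B keeps consensus calls differing from the homozygous
reference; crossing intersects on (chromosome, position) and enforces a
**strictly greater than 5** read count. The 4-fold expression rule is
applied as |log2FC| ≥ 2 — the expression column of the worked table is
in log2 units (its value 2.37 passes the rule only under the log2
reading, so the linear reading would contradict the table itself). Exon
intervals are closed 1-based internally; BED input/output converts at
the boundary and is covered by round-trip tests.

## Attribution and uncertainty

Per-site attribution is described in the README. Reads carrying bases
outside both donor genotypes are always excluded as sequencing error; if
they exceed 5% of depth a warning is raised. Summaries report mean ±
population SD *across SNPs* (the dispersion the ± ranges of this kind of
analysis describe), not a binomial standard error. Default
copy-proportional coefficients are exact thirds (2/3, 1/3) so weighted
counts conserve reads; the literal (0.66, 0.33) option exists because
printed-table arithmetic uses those numerals, at the cost of 1% leakage
(0.66 + 0.33 = 0.99) — both are tested. The two quantitative readings of
the single-het expectation (75/25 majority-allele vs 25/75
donor-derived) correspond to the `allele_ratio` and `unique_allele`
modes; both are implemented because both conventions appear in practice.

The regime test uses, per SNP with a donor1-identifying allele, a
two-sided binomial test against the copy-proportional expectation (1/2
at homozygous-different, 1/4 for the unique allele at donor1-het sites)
with Bonferroni correction at α = 0.05. Verdict rule: `reprogrammed` if
at most half the SNPs reject; `cargo` if most reject *and* the mean
observed/expected ratio is below 0.5; otherwise `ambiguous`;
`inconclusive` with fewer than three testable SNPs. The rule is
intentionally coarse — it distinguishes the two regimes reliably at
depth ≳ 40; at shallow depth the binomial tests are underpowered and the
verdict defaults toward `reprogrammed`.

## Numerical and design choices

* One master seed; each stage (genomes, expression, reads) draws from a
  named substream, so stages are independently reproducible and a run
  manifest suffices to re-run bit-identically.
* Positions are 1-based in all tables (the worked-table convention);
  internal sequence offsets are 0-based half-open.
* Consensus alleles are stored as sorted tuples and rendered `X/Y`;
  comparisons are set-based, since genotypes are unordered.
* Ties in quantile normalization take the average rank (the standard
  convention of the normalization literature); the hand example
  [1,2,3] vs [4,5,6] → both [2.5,3.5,4.5] is frozen in a test.
* Fold changes use a pseudocount of 1 on the linear scale to floor
  zero-expression genes.
* Problem sizes in the tests and the acceptance script (50 sites per
  category at depth ~80; 10^4-read scenario datasets; ~20-site
  parameter-recovery runs) were chosen as the smallest sizes at which
  the binomial sampling error of the reported means is a small fraction
  of the quantities being checked.

## Known limitations

Observed genome-scale numbers from real hybrid sequencing (tens of
thousands of transcriptome SNPs, specific correlation coefficients,
specific observed ratio values) require the original sequencing and
array data and are out of scope; this package reproduces the worked
examples, the theoretical expectations and the statistical machinery,
and validates them on simulation. The consensus caller is not
equivalent to a Bayesian quality-aware caller; the aligner does not do
gapped or spliced alignment; array probe-level processing (background
adjustment, summarization) is not implemented — only the
quantile-normalization and correlation mathematics.
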