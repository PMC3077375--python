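"""Synthetic donor genomes, expression profiles and hybrid transcriptome reads.

The generator emulates the data-generating process the attribution analysis
assumes: two diploid donor genomes ("donor1" = fibroblast-like HEF,
"donor2" = fetal-liver-like hFL) that differ at known exonic SNP sites with
controlled zygosity, fused into a tetraploid (2+2) or octaploid (4+4)
hybrid whose transcriptome is sampled with short single-end reads.

Every read carries ground truth (source donor, haplotype copy and offset),
so downstream alignment, consensus calling and attribution can be checked
against the simulation exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hybridtrace.util import BASES, stage_rng

# SNP zygosity categories the generator can realize
HOM_HOM_DIFF = "HOM_HOM_DIFF"  # both donors homozygous, different alleles
HET_ONE_DONOR1 = "HET_ONE_DONOR1"  # donor1 heterozygous, donor2 homozygous
HET_ONE_DONOR2 = "HET_ONE_DONOR2"  # donor2 heterozygous, donor1 homozygous
HET_BOTH = "HET_BOTH"  # both heterozygous for the same pair
NON_DISCRIMINATING = "NON_DISCRIMINATING"  # identical homozygous genotypes

CATEGORIES = (HOM_HOM_DIFF, HET_ONE_DONOR1, HET_ONE_DONOR2, HET_BOTH, NON_DISCRIMINATING)

GENOTYPE_COLUMNS = [
    "chromosome",
    "position",
    "gene",
    "ref_allele",
    "donor1_genotype",
    "donor2_genotype",
    "truth_category",
]

TRUTH_COLUMNS = [
    "read_id",
    "origin_donor",
    "origin_transcript",
    "origin_copy_index",
    "origin_offset",
    "has_anchor",
]

MISSING_GENOTYPE = "N/A"

# substream keys for the single master seed
_RNG_GENOMES = 1
_RNG_EXPRESSION = 2
_RNG_READS = 3


@dataclass
class SimulationConfig:
    """Parameters of a hybrid-transcriptome simulation.

    coverage is the mean number of reads per expressed transcript copy for
    a gene at the mean baseline expression level; expression_skew is the
    donor1:donor2 relative expression multiplier applied to donor1-derived
    copies (1.0 = balanced hybrid).
    """

    n_genes: int = 8
    transcript_length: int = 500
    snp_counts: Dict[str, int] = field(
        # default mirrors the scale of the worked dozen-SNP example:
        # 11 single-donor-heterozygous sites plus one non-discriminating one
        default_factory=lambda: {
            HOM_HOM_DIFF: 0,
            HET_ONE_DONOR1: 7,
            HET_ONE_DONOR2: 4,
            HET_BOTH: 0,
            NON_DISCRIMINATING: 1,
        }
    )
    read_length: int = 36
    error_rate: float = 0.01
    coverage: float = 60.0
    ploidy_model: str = "tetraploid"  # or "octaploid"
    expression_skew: float = 1.0
    fold_change_spec: Dict[str, float] = field(default_factory=dict)  # gene -> log2FC (hFL over HEF)
    anchor_contamination_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.anchor_contamination_rate < 1):
            raise ValueError("anchor_contamination_rate must be in [0, 1)")
        if self.read_length <= 0 or self.read_length > self.transcript_length:
            raise ValueError("read_length must be in (0, transcript_length]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.expression_skew < 0:
            raise ValueError("expression_skew must be non-negative")
        if self.ploidy_model not in ("tetraploid", "octaploid"):
            raise ValueError("ploidy_model must be 'tetraploid' or 'octaploid'")
        for cat, n in self.snp_counts.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown SNP category {cat!r}")
            if n < 0:
                raise ValueError(f"negative count for category {cat}")
        total = sum(self.snp_counts.values())
        if total > self.n_genes * self.transcript_length:
            raise ValueError("requested more SNP sites than available positions")

    @property
    def copies_per_donor(self) -> int:
        return 2 if self.ploidy_model == "tetraploid" else 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: str


@dataclass
class ReadSet:
    """Simulated reads plus their per-read ground truth.

    The truth table records, for every read id, which donor genome and
    which haplotype copy the read was drawn from and at which 0-based
    transcript offset — the ground-truth surrogate for "which genome was
    the source of a particular transcript".
    """

    reads: List[SimRead]
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read ids")
        if not self.truth.empty and set(ids) != set(self.truth["read_id"]):
            raise ValueError("truth table does not match read ids")

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path) -> None:
        records = [
            SeqRecord(
                Seq(r.sequence),
                id=r.id,
                description="",
                letter_annotations={"phred_quality": [ord(c) - 33 for c in r.quality]},
            )
            for r in self.reads
        ]
        SeqIO.write(records, str(path), "fastq")

    @classmethod
    def read_fastq(cls, path, truth: Optional[pd.DataFrame] = None) -> "ReadSet":
        reads = []
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(SimRead(rec.id, str(rec.seq), qual))
        if truth is None:
            truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        return cls(reads=reads, truth=truth)

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def write_reference(reference: Mapping[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in reference.items()],
        str(path),
        "fasta",
    )


def read_reference(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def generate_donor_genomes(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Generate a transcript reference and a two-donor genotype table.

    Returns ``(reference, genotype_table)`` where the reference maps gene
    symbols to transcript sequences and the table has one row per SNP site
    with 1-based positions and unordered genotype strings (e.g. "CG").
    The reference base is always one of the donor alleles (biallelic
    sites), matching how array-genotyped SNPs behave. All positions not
    listed in the table are identical across all haplotype copies.
    """
    config.validate()
    rng = stage_rng(config.seed, _RNG_GENOMES)

    genes = [f"GENE{i:03d}" for i in range(config.n_genes)]
    reference = {g: _random_sequence(rng, config.transcript_length) for g in genes}

    # lay sites out round-robin across genes, unique positions within a gene
    site_categories: List[str] = []
    for cat in CATEGORIES:
        site_categories.extend([cat] * int(config.snp_counts.get(cat, 0)))
    rng.shuffle(site_categories)

    per_gene_positions: Dict[str, set] = {g: set() for g in genes}
    rows = []
    for i, cat in enumerate(site_categories):
        gene = genes[i % len(genes)]
        if len(per_gene_positions[gene]) >= config.transcript_length:
            raise ValueError(f"too many SNP sites requested for gene {gene}")
        while True:
            pos = int(rng.integers(1, config.transcript_length + 1))  # 1-based
            if pos not in per_gene_positions[gene]:
                per_gene_positions[gene].add(pos)
                break
        ref = reference[gene][pos - 1]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        g1, g2 = _realize_genotypes(rng, cat, ref, alt)
        rows.append((gene, pos, gene, ref, g1, g2, cat))

    table = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    table = table.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
    return reference, table


def _realize_genotypes(
    rng: np.random.Generator, category: str, ref: str, alt: str
) -> Tuple[str, str]:
    """Draw one pair of unordered donor genotypes realizing a category."""
    swap = bool(rng.integers(0, 2))  # which donor carries the ref-homozygous side
    a, b = (ref, alt) if not swap else (alt, ref)
    if category == HOM_HOM_DIFF:
        return a + a, b + b
    if category == HET_ONE_DONOR1:
        return ref + alt, a + a
    if category == HET_ONE_DONOR2:
        return a + a, ref + alt
    if category == HET_BOTH:
        g = ref + alt
        return g, g
    if category == NON_DISCRIMINATING:
        return a + a, a + a
    raise ValueError(f"unknown category {category}")


def generate_expression_profiles(
    reference: Mapping[str, str],
    config: SimulationConfig,
    baseline_mean: float = 100.0,
    baseline_log_sd: float = 0.25,
) -> pd.DataFrame:
    """Per-cell-type linear expression levels (columns ``hFL``, ``HEF``).

    Genes named in ``fold_change_spec`` receive an exact log2 fold change
    (positive = over-expressed in hFL), split symmetrically around a
    shared baseline draw so that hFL/HEF equals 2**log2FC exactly. All
    other genes draw both columns independently from the same log-normal
    baseline distribution.
    """
    config.validate()
    missing = set(config.fold_change_spec) - set(reference)
    if missing:
        raise ValueError(f"fold_change_spec genes absent from reference: {sorted(missing)}")
    rng = stage_rng(config.seed, _RNG_EXPRESSION)
    genes = list(reference)
    mu = np.log(baseline_mean)
    rows = {}
    for g in genes:
        if g in config.fold_change_spec:
            lfc = float(config.fold_change_spec[g])
            base = float(rng.lognormal(mu, baseline_log_sd))
            rows[g] = (base * 2 ** (lfc / 2), base * 2 ** (-lfc / 2))
        else:
            rows[g] = (
                float(rng.lognormal(mu, baseline_log_sd)),
                float(rng.lognormal(mu, baseline_log_sd)),
            )
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=["hFL", "HEF"])
    expr.index.name = "gene"
    if (expr < 0).any().any():
        raise ValueError("negative expression generated")
    return expr


def _haplotype_allele(genotype: str, copy_index: int, ref: str) -> str:
    """Allele carried by one haplotype copy; het genotypes alternate."""
    if genotype == MISSING_GENOTYPE:
        return ref
    return genotype[copy_index % 2]


def build_haplotypes(
    reference: Mapping[str, str],
    genotype_table: pd.DataFrame,
    copies_per_donor: int,
) -> Dict[Tuple[str, int], Dict[str, str]]:
    """Per-(donor, copy) haplotype sequences for every transcript.

    Copy indices run 0..copies_per_donor-1 within each donor; a
    heterozygous genotype "AB" puts allele A on even copies and B on odd
    ones, so a tetraploid heterozygote carries 1+1 and the homozygous
    partner 2 copies of its allele (the 3:1 majority structure).
    """
    haps: Dict[Tuple[str, int], Dict[str, str]] = {}
    by_gene = dict(tuple(genotype_table.groupby("chromosome"))) if len(genotype_table) else {}
    for donor_idx, donor in enumerate(("donor1", "donor2")):
        gcol = f"{donor}_genotype"
        for copy in range(copies_per_donor):
            seqs = {}
            for gene, refseq in reference.items():
                rows = by_gene.get(gene)
                if rows is None:
                    seqs[gene] = refseq
                    continue
                s = list(refseq)
                for _, r in rows.iterrows():
                    s[int(r["position"]) - 1] = _haplotype_allele(
                        str(r[gcol]), copy, str(r["ref_allele"])
                    )
                seqs[gene] = "".join(s)
            haps[(donor, copy)] = seqs
    return haps


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return seq
    idx = np.nonzero(mask)[0]
    base_idx = np.array([BASES.index(chr(b)) for b in arr[idx]])
    new_idx = (base_idx + rng.integers(1, 4, n_err)) % 4
    for i, bi in zip(idx, new_idx):
        arr[i] = ord(BASES[bi])
    return arr.tobytes().decode()


def simulate_hybrid_reads(
    reference: Mapping[str, str],
    genotype_table: pd.DataFrame,
    expression: pd.DataFrame,
    config: SimulationConfig,
    scenario: str = "reprogrammed",
    silencing_factor: float = 0.0,
) -> ReadSet:
    """Draw short single-end reads from the hybrid's haplotype copies.

    Under the "reprogrammed" scenario every copy expresses at the hFL-like
    level (donor1 copies additionally scaled by ``expression_skew``);
    under "cargo" the donor1 (HEF-derived) copies are further multiplied
    by ``silencing_factor`` (0 = fully silent cargo). Reads are drawn
    copy-proportionally (Poisson counts per copy, uniform start
    positions), each base is substituted with probability ``error_rate``,
    and a configurable fraction of reads carries a verbatim UP1/UP2 +
    poly-T anchor prefix.
    """
    config.validate()
    if scenario not in ("reprogrammed", "cargo"):
        raise ValueError("scenario must be 'reprogrammed' or 'cargo'")
    if silencing_factor < 0:
        raise ValueError("silencing_factor must be non-negative")
    rng = stage_rng(config.seed, _RNG_READS)
    # local import: readprep also imports nothing from here, but keep the
    # anchor constants single-sourced
    from hybridtrace.readprep import UP1, UP2

    cpd = config.copies_per_donor
    haps = build_haplotypes(reference, genotype_table, cpd)
    expr_hfl = expression["hFL"]
    mean_level = float(expr_hfl.mean())
    if mean_level <= 0:
        raise ValueError("expression levels must not all be zero")

    L_read = config.read_length
    reads: List[SimRead] = []
    truth_rows = []
    copies = [("donor1", c) for c in range(cpd)] + [("donor2", c) for c in range(cpd)]
    for donor, copy in copies:
        donor_factor = config.expression_skew if donor == "donor1" else 1.0
        if scenario == "cargo" and donor == "donor1":
            donor_factor *= silencing_factor
        for gene, refseq in reference.items():
            lam = config.coverage * donor_factor * float(expr_hfl[gene]) / mean_level
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            hap = haps[(donor, copy)][gene]
            max_start = len(hap) - L_read
            starts = rng.integers(0, max_start + 1, n)
            for start in starts:
                start = int(start)
                seq = hap[start : start + L_read]
                seq = _apply_errors(rng, seq, config.error_rate)
                has_anchor = False
                if config.anchor_contamination_rate > 0 and rng.random() < config.anchor_contamination_rate:
                    anchor = UP1 if rng.integers(0, 2) == 0 else UP2
                    seq = (anchor.primer + seq)[:L_read]
                    has_anchor = True
                rid = f"read{len(reads):07d}"
                global_copy = copy if donor == "donor1" else cpd + copy
                reads.append(SimRead(rid, seq, "I" * len(seq)))
                truth_rows.append((rid, donor, gene, global_copy, start, has_anchor))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return ReadSet(reads=reads, truth=truth)


def coverage_for_depth(
    depth: float, read_length: int, transcript_length: int, total_copies: int = 4
) -> float:
    """Per-copy coverage needed for a target mean per-site depth.

    A read of length m starting uniformly in [0, L-m] covers a given
    interior site with probability ~ m/(L-m+1), so mean depth at a site is
    reads_per_copy * copies * m / (L-m+1).
    """
    window = transcript_length - read_length + 1
    return depth * window / (read_length * total_copies)
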