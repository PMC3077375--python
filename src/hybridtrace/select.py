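"""Discriminating-SNP selection: List A, List B, list crossing and filters.

List A holds array-genotyped exonic sites whose donor genotypes
discriminate the two genomes (homozygous-both-different or heterozygous
in exactly one donor, at most two alleles overall). List B holds sites
where the hybrid transcriptome consensus differs from the reference.
Crossing the lists and requiring a strictly-greater-than read-count
threshold yields the verified SNPs used for attribution; an optional
differential-expression filter restricts to genes with at least a
``min_fold_change``-fold expression difference (applied to |log2FC|).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from hybridtrace.simulate import MISSING_GENOTYPE

logger = logging.getLogger(__name__)

HOM_HOM_DIFF = "HOM_HOM_DIFF"
HET_ONE = "HET_ONE"


@dataclass
class FilterConfig:
    min_read_count: int = 5  # strict: depth must be > this
    min_fold_change: float = 4.0  # linear scale; applied as |log2FC| >= log2(min_fold_change)

    def __post_init__(self) -> None:
        if self.min_read_count < 0 or self.min_fold_change <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def min_abs_log2fc(self) -> float:
        return float(np.log2(self.min_fold_change))


@dataclass(frozen=True)
class InformativeSnp:
    """A discriminating SNP site with its attribution-relevant alleles.

    For HOM_HOM_DIFF sites ``donor1_allele``/``donor2_allele`` are each
    donor's homozygous allele. For HET_ONE sites ``shared_allele`` is the
    allele carried by three of the four tetraploid copies (two from the
    homozygous donor, one from the heterozygous donor) and
    ``unique_allele`` is private to the heterozygous donor.
    """

    chromosome: str
    position: int
    gene: str
    donor1_genotype: str
    donor2_genotype: str
    category: str
    het_donor: Optional[str] = None  # 'donor1' or 'donor2' for HET_ONE
    shared_allele: Optional[str] = None
    unique_allele: Optional[str] = None
    donor1_allele: Optional[str] = None
    donor2_allele: Optional[str] = None


def classify_genotype_pair(g1: str, g2: str) -> Optional[Dict[str, object]]:
    """Classify an unordered donor genotype pair; None if non-discriminating.

    Returns a dict with keys category / het_donor / shared_allele /
    unique_allele / donor1_allele / donor2_allele, or None when the pair
    is missing, identical, heterozygous in both donors, or involves more
    than two distinct alleles (not a biallelic SNP).
    """
    if g1 in (None, MISSING_GENOTYPE) or g2 in (None, MISSING_GENOTYPE):
        return None
    a1, a2 = sorted(g1), sorted(g2)
    if a1 == a2:
        return None  # identical genotypes (incl. both-het same pair)
    if len(set(a1) | set(a2)) > 2:
        return None  # more than two alleles: not a biallelic array SNP
    het1, het2 = a1[0] != a1[1], a2[0] != a2[1]
    if het1 and het2:
        return None  # both heterozygous
    if not het1 and not het2:
        return {
            "category": HOM_HOM_DIFF,
            "het_donor": None,
            "shared_allele": None,
            "unique_allele": None,
            "donor1_allele": a1[0],
            "donor2_allele": a2[0],
        }
    het_donor = "donor1" if het1 else "donor2"
    het_pair, hom = (a1, a2[0]) if het1 else (a2, a1[0])
    if hom not in het_pair:
        return None  # three alleles; unreachable after the set check above
    unique = het_pair[0] if het_pair[1] == hom else het_pair[1]
    return {
        "category": HET_ONE,
        "het_donor": het_donor,
        "shared_allele": hom,
        "unique_allele": unique,
        "donor1_allele": None,
        "donor2_allele": None,
    }


class ExonAnnotation:
    """Closed 1-based exon intervals per chromosome (BED files convert on read)."""

    def __init__(self, intervals: Mapping[str, Sequence[Tuple[int, int]]]):
        self.intervals = {c: sorted(ivs) for c, ivs in intervals.items()}

    def contains(self, chromosome: str, position: int) -> bool:
        for start, end in self.intervals.get(str(chromosome), ()):
            if start <= position <= end:
                return True
        return False

    @classmethod
    def from_bed(cls, path) -> "ExonAnnotation":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], dtype={"chrom": str})
        ivs: Dict[str, List[Tuple[int, int]]] = {}
        for _, r in df.iterrows():
            # BED is 0-based half-open; internal convention is closed 1-based
            ivs.setdefault(r["chrom"], []).append((int(r["start"]) + 1, int(r["end"])))
        return cls(ivs)

    def to_bed(self, path) -> None:
        rows = [
            (c, s - 1, e)
            for c, ivs in sorted(self.intervals.items())
            for s, e in ivs
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _snps_to_frame(snps: Sequence[InformativeSnp]) -> pd.DataFrame:
    cols = [
        "chromosome",
        "position",
        "gene",
        "donor1_genotype",
        "donor2_genotype",
        "category",
        "het_donor",
        "shared_allele",
        "unique_allele",
        "donor1_allele",
        "donor2_allele",
    ]
    return pd.DataFrame([vars(s) for s in snps], columns=cols)


def build_list_a(
    genotype_table: pd.DataFrame,
    exon_annotation: Optional[ExonAnnotation] = None,
    expression_log2fc: Optional[pd.Series] = None,
    config: FilterConfig = FilterConfig(),
) -> Tuple[List[InformativeSnp], Dict[str, int]]:
    """Array-side discriminating SNPs, via the ordered filter cascade.

    Cascade: exonic (if an annotation is given) -> discriminating donor
    genotypes (missing N/A genotypes excluded) -> differential expression
    (if per-gene log2 fold changes are given). Returns the SNPs sorted by
    (chromosome, position) and the per-stage row counts.
    """
    stages: Dict[str, int] = {"input": len(genotype_table)}
    df = genotype_table
    if exon_annotation is not None:
        keep = df.apply(
            lambda r: exon_annotation.contains(str(r["chromosome"]), int(r["position"])), axis=1
        )
        df = df[keep] if len(df) else df
    stages["exonic"] = len(df)

    snps: List[InformativeSnp] = []
    for _, r in df.iterrows():
        cls = classify_genotype_pair(str(r["donor1_genotype"]), str(r["donor2_genotype"]))
        if cls is None:
            continue
        snps.append(
            InformativeSnp(
                chromosome=str(r["chromosome"]),
                position=int(r["position"]),
                gene=str(r["gene"]),
                donor1_genotype=str(r["donor1_genotype"]),
                donor2_genotype=str(r["donor2_genotype"]),
                **cls,
            )
        )
    stages["discriminating"] = len(snps)

    if expression_log2fc is not None:
        kept = []
        for s in snps:
            if s.gene not in expression_log2fc.index:
                warnings.warn(f"gene {s.gene} missing from expression table; SNP excluded")
                continue
            if abs(float(expression_log2fc[s.gene])) >= config.min_abs_log2fc:
                kept.append(s)
        snps = kept
        stages["differential_expression"] = len(snps)

    snps.sort(key=lambda s: (s.chromosome, s.position))
    logger.info("list A cascade: %s", stages)
    return snps, stages


def build_list_b(
    consensus_df: pd.DataFrame,
    exon_annotation: Optional[ExonAnnotation] = None,
) -> pd.DataFrame:
    """Transcriptome-side SNPs: sites whose consensus is not the homozygous reference."""
    if consensus_df.empty:
        return consensus_df.copy()
    is_variant = consensus_df["consensus"] != consensus_df["ref_allele"]
    df = consensus_df[is_variant]
    if exon_annotation is not None and len(df):
        keep = df.apply(
            lambda r: exon_annotation.contains(str(r["chromosome"]), int(r["position"])), axis=1
        )
        df = df[keep]
    return df.reset_index(drop=True)


def cross_lists(
    list_a: Sequence[InformativeSnp],
    list_b: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Intersect the lists on (chromosome, position) and apply the depth rule.

    Rows with transcriptome depth <= ``min_read_count`` (strict '>') are
    removed; the output carries both the array genotypes and the
    transcriptome counts.
    """
    a = _snps_to_frame(list(list_a))
    if a.empty or list_b.empty:
        return pd.DataFrame(columns=list(a.columns) + [c for c in list_b.columns if c not in ("chromosome", "position")])
    for df, name in ((a, "list A"), (list_b, "list B")):
        dup = df.duplicated(subset=["chromosome", "position"])
        if dup.any():
            raise ValueError(f"duplicate (chromosome, position) keys in {name}")
    a["chromosome"] = a["chromosome"].astype(str)
    b = list_b.copy()
    b["chromosome"] = b["chromosome"].astype(str)
    merged = a.merge(b, on=["chromosome", "position"], how="inner", suffixes=("", "_b"))
    merged = merged[merged["depth"] > config.min_read_count]
    return merged.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)


def de_filter(
    snps: pd.DataFrame,
    expression_log2fc: pd.Series,
    config: FilterConfig = FilterConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Split SNPs in sufficiently differentially expressed genes into up/down.

    Keeps rows whose gene satisfies |log2FC| >= log2(min_fold_change),
    split by the sign of the fold change (positive = up in the
    hFL/erythroid direction). Returns (up, down, summary counts).
    """
    if snps.empty:
        empty = snps.copy()
        return empty, empty.copy(), {"up_snps": 0, "up_genes": 0, "down_snps": 0, "down_genes": 0}
    lfc = snps["gene"].map(expression_log2fc)
    passing = lfc.abs() >= config.min_abs_log2fc
    up = snps[passing & (lfc > 0)].reset_index(drop=True)
    down = snps[passing & (lfc < 0)].reset_index(drop=True)
    summary = {
        "up_snps": len(up),
        "up_genes": up["gene"].nunique() if len(up) else 0,
        "down_snps": len(down),
        "down_genes": down["gene"].nunique() if len(down) else 0,
    }
    logger.info("differential-expression split: %s", summary)
    return up, down, summary


def snps_from_frame(df: pd.DataFrame) -> List[InformativeSnp]:
    """Rebuild InformativeSnp objects from a crossed/selected table."""
    out = []
    for _, r in df.iterrows():
        out.append(
            InformativeSnp(
                chromosome=str(r["chromosome"]),
                position=int(r["position"]),
                gene=str(r["gene"]),
                donor1_genotype=str(r["donor1_genotype"]),
                donor2_genotype=str(r["donor2_genotype"]),
                category=str(r["category"]),
                het_donor=None if pd.isna(r.get("het_donor")) else str(r["het_donor"]),
                shared_allele=None if pd.isna(r.get("shared_allele")) else str(r["shared_allele"]),
                unique_allele=None if pd.isna(r.get("unique_allele")) else str(r["unique_allele"]),
                donor1_allele=None if pd.isna(r.get("donor1_allele")) else str(r["donor1_allele"]),
                donor2_allele=None if pd.isna(r.get("donor2_allele")) else str(r["donor2_allele"]),
            )
        )
    return out
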