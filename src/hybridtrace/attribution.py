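"""Copy-number-weighted attribution of reads to their genome of origin.

In a balanced tetraploid hybrid each donor contributes two haplotype
copies, so read counts at discriminating SNP sites carry the signature of
which genome is transcribed:

* HOM_HOM_DIFF sites (donors homozygous for different alleles): each
  allele identifies its donor outright; 2+2 copies give a theoretical
  50%/50% read split.
* HET_ONE sites (one donor heterozygous): the shared allele sits on three
  copies and the heterozygous donor's unique allele on one, so the
  majority allele's theoretical read share is 75% and the unique allele's
  25%.

Three attribution conventions are implemented. ``allele_ratio`` reports
majority/minority allele fractions without splitting by donor.
``copy_proportional`` splits the shared allele's reads 2/3 to the
homozygous donor and 1/3 to the heterozygous donor (exact thirds conserve
reads; the literal 0.66/0.33 coefficient option reproduces printed-table
arithmetic at the cost of 1% leakage). ``unique_allele`` assigns the
shared allele wholly to the homozygous donor and the unique allele wholly
to the heterozygous donor, which reproduces the 25%/75% expectation for
the heterozygous donor's share.

The model/results pair follows the usual estimator layout: build an
:class:`OriginAttributionModel` from selected SNPs and pileup counts,
``fit()`` it, and read per-SNP records, category summaries (mean ± SD
across SNPs against the theoretical expectation) and the silent-cargo
scenario test off the results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from hybridtrace.align import PileupCounts
from hybridtrace.select import HET_ONE, HOM_HOM_DIFF, InformativeSnp
from hybridtrace.util import format_percent

MODES = ("allele_ratio", "copy_proportional", "unique_allele")


@dataclass
class AttributionConfig:
    mode: str = "copy_proportional"
    major_share: float = 2.0 / 3.0  # shared-allele coefficient for the homozygous donor
    minor_share: float = 1.0 / 3.0  # shared-allele coefficient for the heterozygous donor
    error_budget: float = 0.05  # tolerated off-genotype fraction of depth

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.major_share + self.minor_share > 1.0 + 1e-12:
            raise ValueError("major_share + minor_share must be <= 1")

    @classmethod
    def literal(cls, mode: str = "copy_proportional") -> "AttributionConfig":
        """The printed-table coefficient variant (0.66 / 0.33).

        These do not sum to 1, so weighted counts lose 1% of shared-allele
        reads; provided only to reproduce that arithmetic verbatim.
        """
        return cls(mode=mode, major_share=0.66, minor_share=0.33)


@dataclass
class AttributionRecord:
    snp: InformativeSnp
    counts: Dict[str, int]  # raw counts of the discriminating alleles
    informative_depth: int
    excluded_offgenotype: int
    weighted_donor1: float  # HEF-like donor
    weighted_donor2: float  # hFL-like donor
    fraction_donor1: float
    fraction_donor2: float
    majority_fraction: float  # HET_ONE only (shared-allele share); NaN for HOM


def attribute_reads(
    snp: InformativeSnp,
    base_counts: Mapping[str, int],
    config: AttributionConfig = AttributionConfig(),
) -> AttributionRecord:
    """Attribute one site's read counts to the two donor genomes.

    Reads carrying bases outside both donor genotypes are excluded as
    sequencing error; if they exceed ``error_budget`` of the site depth a
    warning is raised.
    """
    depth = sum(int(v) for v in base_counts.values())
    if snp.category == HOM_HOM_DIFF:
        alleles = [snp.donor1_allele, snp.donor2_allele]
    elif snp.category == HET_ONE:
        alleles = [snp.shared_allele, snp.unique_allele]
    else:
        raise ValueError(f"cannot attribute category {snp.category}")
    counts = {a: int(base_counts.get(a, 0)) for a in alleles}
    informative = sum(counts.values())
    excluded = depth - informative
    if depth > 0 and excluded > config.error_budget * depth:
        warnings.warn(
            f"{snp.chromosome}:{snp.position}: {excluded}/{depth} reads carry "
            "off-genotype alleles (over the sequencing-error budget); excluded"
        )
    if informative == 0:
        raise ValueError(f"no informative reads at {snp.chromosome}:{snp.position}")

    nan = float("nan")
    if snp.category == HOM_HOM_DIFF:
        w1 = float(counts[snp.donor1_allele])  # coefficient 1: wholly attributed
        w2 = float(counts[snp.donor2_allele])
        f1, f2 = w1 / informative, w2 / informative
        majority = nan
    else:
        shared = counts[snp.shared_allele]
        unique = counts[snp.unique_allele]
        majority = shared / informative
        if config.mode == "allele_ratio":
            w1 = w2 = f1 = f2 = nan
        else:
            if config.mode == "copy_proportional":
                hom_w = config.major_share * shared
                het_w = unique + config.minor_share * shared
            else:  # unique_allele
                hom_w = float(shared)
                het_w = float(unique)
            if snp.het_donor == "donor1":
                w1, w2 = het_w, hom_w
            else:
                w1, w2 = hom_w, het_w
            f1, f2 = w1 / (w1 + w2), w2 / (w1 + w2)
    return AttributionRecord(
        snp=snp,
        counts=counts,
        informative_depth=informative,
        excluded_offgenotype=excluded,
        weighted_donor1=w1,
        weighted_donor2=w2,
        fraction_donor1=f1,
        fraction_donor2=f2,
        majority_fraction=majority,
    )


def theoretical_expectation(category: str, mode: str, het_donor: Optional[str] = None) -> Dict[str, float]:
    """Theoretical per-site expectations for a balanced hybrid.

    Keyed by the statistic each mode reports: donor fractions for
    HOM_HOM_DIFF (1/2 each), the majority-allele share for HET_ONE in
    allele_ratio mode (3/4), the heterozygous donor's share in
    unique_allele mode (1/4) and in copy_proportional mode (1/2).
    """
    if category == HOM_HOM_DIFF:
        return {"fraction_donor1": 0.5, "fraction_donor2": 0.5}
    if category != HET_ONE:
        raise ValueError(category)
    if mode == "allele_ratio":
        return {"majority_fraction": 0.75}
    het_frac = 0.25 if mode == "unique_allele" else 0.5
    out = {"het_donor_fraction": het_frac}
    if het_donor == "donor1":
        out.update({"fraction_donor1": het_frac, "fraction_donor2": 1 - het_frac})
    elif het_donor == "donor2":
        out.update({"fraction_donor2": het_frac, "fraction_donor1": 1 - het_frac})
    return out


class OriginAttributionModel:
    """Genome-of-origin attribution over a set of discriminating SNPs.

    Parameters
    ----------
    snps : informative SNP sites (HOM_HOM_DIFF or HET_ONE).
    counts_by_site : mapping of (chromosome, position) to per-base read
        counts from the hybrid transcriptome pileup.
    config : attribution convention and coefficients.
    """

    def __init__(
        self,
        snps: Sequence[InformativeSnp],
        counts_by_site: Mapping[Tuple[str, int], Mapping[str, int]],
        config: AttributionConfig = AttributionConfig(),
    ):
        self.snps = list(snps)
        self.counts_by_site = dict(counts_by_site)
        self.config = config

    @classmethod
    def from_pileup(
        cls,
        snps: Sequence[InformativeSnp],
        pile: PileupCounts,
        config: AttributionConfig = AttributionConfig(),
    ) -> "OriginAttributionModel":
        counts = {
            (s.chromosome, s.position): pile.base_counts(s.chromosome, s.position) for s in snps
        }
        return cls(snps, counts, config)

    def fit(self) -> "OriginAttributionResults":
        records = []
        skipped = 0
        for snp in self.snps:
            key = (snp.chromosome, snp.position)
            counts = self.counts_by_site.get(key)
            if counts is None or sum(counts.values()) == 0:
                skipped += 1
                continue
            records.append(attribute_reads(snp, counts, self.config))
        if skipped:
            warnings.warn(f"{skipped} SNP site(s) had no coverage and were skipped")
        return OriginAttributionResults(records, self.config)


class OriginAttributionResults:
    """Fitted attribution: per-SNP records plus category-level summaries."""

    def __init__(self, records: Sequence[AttributionRecord], config: AttributionConfig):
        self.records = list(records)
        self.config = config

    @property
    def frame(self) -> pd.DataFrame:
        """One row per SNP: category, raw and weighted counts, fractions."""
        rows = []
        for r in self.records:
            s = r.snp
            rows.append(
                {
                    "chromosome": s.chromosome,
                    "position": s.position,
                    "gene": s.gene,
                    "category": s.category,
                    "het_donor": s.het_donor,
                    "counts": ";".join(f"{a}={c}" for a, c in r.counts.items()),
                    "informative_depth": r.informative_depth,
                    "excluded_offgenotype": r.excluded_offgenotype,
                    "weighted_donor1": r.weighted_donor1,
                    "weighted_donor2": r.weighted_donor2,
                    "fraction_donor1": r.fraction_donor1,
                    "fraction_donor2": r.fraction_donor2,
                    "majority_fraction": r.majority_fraction,
                }
            )
        return pd.DataFrame(rows)

    def _groups(self):
        homs = [r for r in self.records if r.snp.category == HOM_HOM_DIFF]
        hets = [r for r in self.records if r.snp.category == HET_ONE]
        return homs, hets

    def summary(self) -> pd.DataFrame:
        """Per-category mean ± SD (population SD across SNPs) vs theory.

        Empty categories are omitted with a warning. Statistics reported:
        the donor-2 (hFL-like) read fraction for HOM_HOM_DIFF sites
        (theoretical 1/2), and per heterozygous donor for HET_ONE sites
        either the majority-allele share (allele_ratio mode, theoretical
        3/4) or the heterozygous donor's attributed share (1/4 in
        unique_allele mode, 1/2 in copy_proportional mode).
        """
        homs, hets = self._groups()
        rows = []
        if homs:
            vals = np.array([r.fraction_donor2 for r in homs])
            rows.append(self._summary_row(HOM_HOM_DIFF, None, "fraction_donor2", vals, 0.5))
        else:
            warnings.warn("no HOM_HOM_DIFF records; category omitted from summary")
        if hets:
            if self.config.mode == "allele_ratio":
                vals = np.array([r.majority_fraction for r in hets])
                rows.append(self._summary_row(HET_ONE, None, "majority_fraction", vals, 0.75))
            else:
                theo = 0.25 if self.config.mode == "unique_allele" else 0.5
                for donor in ("donor1", "donor2"):
                    sub = [r for r in hets if r.snp.het_donor == donor]
                    if not sub:
                        continue
                    vals = np.array(
                        [r.fraction_donor1 if donor == "donor1" else r.fraction_donor2 for r in sub]
                    )
                    rows.append(
                        self._summary_row(HET_ONE, donor, f"fraction_{donor}", vals, theo)
                    )
        else:
            warnings.warn("no HET_ONE records; category omitted from summary")
        return pd.DataFrame(
            rows,
            columns=[
                "category",
                "het_donor",
                "statistic",
                "n_snps",
                "mean",
                "sd",
                "theoretical",
                "mean_percent",
                "sd_percent",
            ],
        )

    @staticmethod
    def _summary_row(category, het_donor, statistic, vals, theoretical):
        mean = float(np.mean(vals))
        sd = float(np.std(vals))  # population SD across SNPs
        return {
            "category": category,
            "het_donor": het_donor,
            "statistic": statistic,
            "n_snps": len(vals),
            "mean": mean,
            "sd": sd,
            "theoretical": theoretical,
            "mean_percent": format_percent(mean),
            "sd_percent": format_percent(sd),
        }


@dataclass
class RegimeReport:
    """Outcome of the silent-cargo vs reprogrammed regime test."""

    verdict: str  # 'reprogrammed' | 'cargo' | 'ambiguous' | 'inconclusive'
    n_snps: int
    n_rejected: int
    mean_observed_over_expected: float
    alpha: float
    pvalues: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def classify_regime(
    results: OriginAttributionResults,
    alpha: float = 0.05,
    min_snps: int = 3,
) -> RegimeReport:
    """Decide whether the data match the reprogrammed or silent-cargo regime.

    Each SNP with a donor1-identifying (HEF-side) allele — HOM_HOM_DIFF
    sites (expected read share 1/2) and HET_ONE sites where donor1 is
    heterozygous (unique-allele share 1/4) — is tested with a two-sided
    binomial test against its copy-proportional expectation; rejections
    use a Bonferroni-corrected alpha. Verdict: 'reprogrammed' if at most
    half the SNPs reject, 'cargo' if most reject and donor1 alleles are
    depleted below half their expectation, else 'ambiguous';
    'inconclusive' below ``min_snps`` covered sites.
    """
    rows = []
    for r in results.records:
        s = r.snp
        if s.category == HOM_HOM_DIFF:
            k, p_exp = r.counts[s.donor1_allele], 0.5
        elif s.category == HET_ONE and s.het_donor == "donor1":
            k, p_exp = r.counts[s.unique_allele], 0.25
        else:
            continue
        n = r.informative_depth
        pval = binomtest(k, n, p_exp, alternative="two-sided").pvalue
        rows.append(
            {
                "chromosome": s.chromosome,
                "position": s.position,
                "category": s.category,
                "k_donor1": k,
                "n": n,
                "expected": p_exp,
                "observed": k / n,
                "pvalue": pval,
            }
        )
    pvals = pd.DataFrame(rows)
    m = len(pvals)
    if m < min_snps:
        return RegimeReport("inconclusive", m, 0, float("nan"), alpha, pvals)
    reject = pvals["pvalue"] < alpha / m  # Bonferroni
    n_rej = int(reject.sum())
    ratio = float((pvals["observed"] / pvals["expected"]).mean())
    if n_rej <= m / 2:
        verdict = "reprogrammed"
    elif ratio < 0.5:
        verdict = "cargo"
    else:
        verdict = "ambiguous"
    return RegimeReport(verdict, m, n_rej, ratio, alpha, pvals)


def scenario_test(
    results_by_scenario: Mapping[str, OriginAttributionResults],
    alpha: float = 0.05,
) -> Dict[str, RegimeReport]:
    """Run the regime classification for each fitted scenario dataset."""
    return {name: classify_regime(res, alpha=alpha) for name, res in results_by_scenario.items()}
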