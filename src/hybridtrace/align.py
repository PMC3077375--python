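"""Desk-scale unique alignment, pileup and consensus genotype calling.

The aligner is an exact k-mer seed + ungapped extension mapper: a read is
reported iff exactly one reference location matches within
``max_mismatches`` (both strands searched); multi-hits and ties are
discarded. Seeds are taken every k bases plus one flush with the read
end, so any alignment with at most floor(len/k)-1 mismatches is
guaranteed to be seeded (pigeonhole); at the 36 nt / k=12 / 2-mismatch
defaults detection is therefore exhaustive.

The consensus caller ranks bases by count (lexicographic tie-break) and
calls a heterozygote when the second-best base is supported by at least
``max(min_minor_reads, minor_fraction * depth)`` reads — a deliberately
simple frequency rule standing in for a full Bayesian re-sequencing
caller, validated on simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from hybridtrace.simulate import ReadSet
from hybridtrace.util import BASES, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class Alignment:
    read_id: str
    transcript: str
    offset: int  # 0-based on the reference forward strand
    strand: str  # '+' or '-'
    mismatches: int
    aligned_seq: str  # read sequence in reference orientation


@dataclass
class AlignmentStats:
    n_reads: int = 0
    n_unique: int = 0
    n_multi: int = 0
    n_unaligned: int = 0


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance, early-exit above limit (returns limit+1)."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return limit + 1
    return mm


def _build_index(reference: Mapping[str, str], k: int) -> Dict[str, List[Tuple[str, int]]]:
    index: Dict[str, List[Tuple[str, int]]] = {}
    for name, seq in reference.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def align_reads(
    readset: ReadSet | Sequence,
    reference: Mapping[str, str],
    max_mismatches: int = 2,
    seed_k: int = 12,
) -> Tuple[List[Alignment], AlignmentStats]:
    """Uniquely align reads to the transcript reference, ungapped.

    Returns the unique alignments and counts of multi-hit / unaligned
    reads. A read aligning equally well (or within the mismatch bound) at
    more than one location is discarded as non-unique.
    """
    if not reference:
        raise ValueError("empty reference")
    reads = readset.reads if isinstance(readset, ReadSet) else list(readset)
    index = _build_index(reference, seed_k)
    ref_lens = {name: len(seq) for name, seq in reference.items()}
    alignments: List[Alignment] = []
    stats = AlignmentStats(n_reads=len(reads))
    for read in reads:
        m = len(read.sequence)
        if m < seed_k:
            stats.n_unaligned += 1
            continue
        hits: Dict[Tuple[str, int, str], int] = {}
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            candidates = set()
            offsets = list(range(0, m - seed_k + 1, seed_k))
            if offsets[-1] != m - seed_k:
                offsets.append(m - seed_k)
            for off in offsets:
                for tname, pos in index.get(seq[off : off + seed_k], ()):
                    start = pos - off
                    if 0 <= start <= ref_lens[tname] - m:
                        candidates.add((tname, start))
            for tname, start in candidates:
                mm = _mismatches(seq, reference[tname][start : start + m], max_mismatches)
                if mm <= max_mismatches:
                    hits[(tname, start, strand)] = mm
        if len(hits) == 0:
            stats.n_unaligned += 1
        elif len(hits) == 1:
            (tname, start, strand), mm = next(iter(hits.items()))
            seq = read.sequence if strand == "+" else revcomp(read.sequence)
            alignments.append(Alignment(read.id, tname, start, strand, mm, seq))
            stats.n_unique += 1
        else:
            stats.n_multi += 1
    return alignments, stats


class PileupCounts:
    """Per-site base counts over the reference, from unique alignments only."""

    def __init__(self, reference: Mapping[str, str]):
        self.reference = dict(reference)
        self.counts: Dict[str, np.ndarray] = {
            name: np.zeros((4, len(seq)), dtype=np.int64) for name, seq in reference.items()
        }

    def add(self, alignment: Alignment) -> None:
        arr = self.counts[alignment.transcript]
        for j, base in enumerate(alignment.aligned_seq):
            bi = _BASE_INDEX.get(base)
            if bi is not None:  # N excluded from depth
                arr[bi, alignment.offset + j] += 1

    def base_counts(self, transcript: str, position: int) -> Dict[str, int]:
        """Counts per base at a 1-based position."""
        col = self.counts[transcript][:, position - 1]
        return {b: int(col[i]) for i, b in enumerate(BASES)}

    def depth(self, transcript: str, position: int) -> int:
        return int(self.counts[transcript][:, position - 1].sum())

    def covered_sites(self) -> Iterable[Tuple[str, int]]:
        for name, arr in self.counts.items():
            for pos0 in np.nonzero(arr.sum(axis=0))[0]:
                yield name, int(pos0) + 1


def pileup(alignments: Iterable[Alignment], reference: Mapping[str, str]) -> PileupCounts:
    """Tally aligned read bases per reference site (depth = sum of ACGT counts)."""
    p = PileupCounts(reference)
    for aln in alignments:
        p.add(aln)
    return p


@dataclass
class SiteCall:
    """Consensus call at one site, in the 1st/2nd-best-base dialect."""

    transcript: str
    position: int  # 1-based
    depth: int
    base_counts: Dict[str, int]
    first_best: Tuple[str, int]
    second_best: Optional[Tuple[str, int]]
    consensus: Tuple[str, ...]  # sorted allele tuple: ('G',) or ('C','G')

    @property
    def is_het(self) -> bool:
        return len(self.consensus) == 2

    def consensus_string(self) -> str:
        return "/".join(self.consensus)

    def freq_string(self, which: int) -> str:
        best = self.first_best if which == 1 else self.second_best
        if best is None:
            return ""
        return f"{best[1]}\\{self.depth}"


def call_consensus(
    base_counts: Mapping[str, int],
    transcript: str = "",
    position: int = 0,
    min_minor_reads: int = 2,
    minor_fraction: float = 0.2,
) -> Optional[SiteCall]:
    """Call the consensus genotype at one site from its base counts.

    The first-best base is the count argmax (ties broken by alphabetical
    order); the call is heterozygous first/second-best iff the second-best
    count reaches ``max(min_minor_reads, minor_fraction * depth)``, else
    homozygous first-best. Depth 0 yields no call.
    """
    counts = {b: int(base_counts.get(b, 0)) for b in BASES}
    depth = sum(counts.values())
    if depth == 0:
        return None
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    first = ranked[0]
    second = ranked[1] if ranked[1][1] > 0 else None
    threshold = max(min_minor_reads, minor_fraction * depth)
    if second is not None and second[1] >= threshold:
        consensus = tuple(sorted((first[0], second[0])))
    else:
        consensus = (first[0],)
    return SiteCall(transcript, position, depth, counts, first, second, consensus)


CONSENSUS_COLUMNS = [
    "chromosome",
    "position",
    "ref_allele",
    "consensus",
    "first_best_base",
    "first_best_count",
    "second_best_base",
    "second_best_count",
    "depth",
    "first_best_freq",
    "second_best_freq",
]


def consensus_table(
    pile: PileupCounts,
    sites: Optional[Iterable[Tuple[str, int]]] = None,
    min_depth: int = 1,
    min_minor_reads: int = 2,
    minor_fraction: float = 0.2,
) -> pd.DataFrame:
    """Consensus calls as a table (the printed-table dialect, one row per site).

    ``sites`` restricts the output to chosen (transcript, 1-based
    position) pairs; by default every covered site is called. Frequencies
    are rendered as ``count\\depth`` strings.
    """
    if sites is None:
        sites = pile.covered_sites()
    rows = []
    for transcript, position in sites:
        counts = pile.base_counts(transcript, position)
        call = call_consensus(
            counts, transcript, position, min_minor_reads=min_minor_reads, minor_fraction=minor_fraction
        )
        if call is None or call.depth < min_depth:
            continue
        ref = pile.reference[transcript][position - 1]
        rows.append(
            {
                "chromosome": transcript,
                "position": position,
                "ref_allele": ref,
                "consensus": call.consensus_string(),
                "first_best_base": call.first_best[0],
                "first_best_count": call.first_best[1],
                "second_best_base": call.second_best[0] if call.second_best else "",
                "second_best_count": call.second_best[1] if call.second_best else 0,
                "depth": call.depth,
                "first_best_freq": call.freq_string(1),
                "second_best_freq": call.freq_string(2),
            }
        )
    return pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)
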