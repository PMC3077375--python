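"""cDNA-library cleanup: UP1/UP2 anchor detection and removal.

The library protocol anchors reverse transcription with primers built as
unique sequence + BstU1 site (CGCG) + poly-T; reads that start inside a
primer therefore carry the anchor and a poly-T run before any insert.
This module provides in-silico BstU1 digestion (CG^CG, blunt) and a
prefix-matching trimmer that removes anchor + poly-T and drops reads that
become too short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import pandas as pd

from hybridtrace.simulate import ReadSet, SimRead

BSTU1_SITE = "CGCG"
_CUT_OFFSET = 2  # CG^CG


@dataclass(frozen=True)
class AnchorSpec:
    """One anchor primer: unique sequence ending in the BstU1 site, then poly-T."""

    name: str
    sequence: str  # anchor portion (unique sequence + CGCG), without the poly-T
    polyt_length: int = 24
    restriction_site: str = BSTU1_SITE

    def __post_init__(self) -> None:
        if self.restriction_site not in self.sequence:
            raise ValueError(
                f"anchor {self.name}: restriction site {self.restriction_site} "
                "not found in sequence"
            )

    @property
    def primer(self) -> str:
        """Full primer: anchor followed by the poly-T tract."""
        return self.sequence + "T" * self.polyt_length


# Verbatim primer sequences (spaces removed); each is 28 nt of unique
# sequence + CGCG followed by 24 T.
UP1 = AnchorSpec("UP1", "ATATGGATCCGGCGCGCCGTCGACCGCG")
UP2 = AnchorSpec("UP2", "ATATCTCGAGGGCGCGCCGGATCCCGCG")

DEFAULT_ANCHORS: Tuple[AnchorSpec, ...] = (UP1, UP2)

# a primer-derived poly-T tract is at least this long
MIN_POLYT_RUN = 10


def digest_bstu1(sequence: str) -> List[str]:
    """Split a sequence at every BstU1 site (CG^CG), left to right.

    The scan resumes at each cut point, so chained sites (CGCGCG...) are
    fully digested. Concatenating the fragments reproduces the input;
    an empty sequence yields one empty fragment.
    """
    fragments: List[str] = []
    prev = 0
    i = sequence.find(BSTU1_SITE)
    while i != -1:
        cut = i + _CUT_OFFSET
        fragments.append(sequence[prev:cut])
        prev = cut
        i = sequence.find(BSTU1_SITE, cut)
    fragments.append(sequence[prev:])
    return fragments


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _trim_once(seq: str, specs: Sequence[AnchorSpec], max_mismatches: int) -> Tuple[str, bool]:
    for spec in specs:
        n = min(len(spec.sequence), len(seq))
        if n == 0:
            continue
        # a read shorter than the anchor can still be pure anchor prefix
        if _hamming_at_most(seq[:n], spec.sequence[:n], max_mismatches):
            rest = seq[n:]
            rest = rest.lstrip("T")  # primer-derived poly-T tract
            return rest, True
    return seq, False


@dataclass
class TrimReport:
    n_in: int = 0
    n_trimmed: int = 0
    n_dropped: int = 0

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_dropped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("reads_in", self.n_in),
                ("reads_trimmed", self.n_trimmed),
                ("reads_dropped", self.n_dropped),
                ("reads_out", self.n_out),
            ],
            columns=["metric", "value"],
        )


def trim_anchors(
    readset: ReadSet,
    specs: Sequence[AnchorSpec] = DEFAULT_ANCHORS,
    max_mismatches: int = 1,
    min_length: int = 20,
) -> Tuple[ReadSet, TrimReport]:
    """Remove anchor + poly-T prefixes; drop reads left shorter than ``min_length``.

    A read whose prefix matches an anchor within ``max_mismatches`` loses
    the anchor and every following T (the primer's poly-T tract). Trimming
    repeats until no anchor prefix remains, which makes the operation
    idempotent. The truth table (if any) is subset to surviving reads.
    """
    report = TrimReport(n_in=len(readset))
    out: List[SimRead] = []
    kept_ids = []
    for read in readset.reads:
        seq = read.sequence
        trimmed_any = False
        while True:
            seq, did = _trim_once(seq, specs, max_mismatches)
            if not did:
                break
            trimmed_any = True
        if trimmed_any:
            report.n_trimmed += 1
        if len(seq) < min_length:
            report.n_dropped += 1
            continue
        qual = read.quality[len(read.sequence) - len(seq) :] if read.quality else ""
        out.append(SimRead(read.id, seq, qual))
        kept_ids.append(read.id)
    truth = readset.truth
    if not truth.empty:
        truth = truth[truth["read_id"].isin(set(kept_ids))].reset_index(drop=True)
    return ReadSet(reads=out, truth=truth), report
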