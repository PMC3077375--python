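"""Small shared helpers."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


def fusion_efficiency(colonies: int, input_cells: float) -> float:
    """Fusion/amplification efficiency as a percentage.

    Each colony is assumed to be the progeny of a single hybrid cell, so
    the efficiency is simply colonies per input cell, expressed in percent
    (e.g. 363 colonies from 2x10^6 cells -> 0.018%).
    """
    if colonies < 0 or input_cells <= 0:
        raise ValueError("colonies must be >= 0 and input_cells > 0")
    return 100.0 * colonies / input_cells


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Named RNG substream: one master seed, one fixed key per stage."""
    return np.random.default_rng([int(seed), int(stage)])


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction in the percent dialect, e.g. 0.7331 -> '73.3%'."""
    return f"{100.0 * fraction:.{decimals}f}%"
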