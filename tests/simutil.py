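"""Shared test helper: run one simulation through alignment and SNP selection."""

import warnings
from types import SimpleNamespace

from hybridtrace.align import align_reads, pileup
from hybridtrace.select import build_list_a
from hybridtrace.simulate import (
    generate_donor_genomes,
    generate_expression_profiles,
    simulate_hybrid_reads,
)


def run_simulation(config, scenario="reprogrammed", silencing_factor=0.0, align=True):
    """Simulate and (optionally) align one dataset; returns all intermediates."""
    reference, genotypes = generate_donor_genomes(config)
    expression = generate_expression_profiles(reference, config)
    readset = simulate_hybrid_reads(
        reference, genotypes, expression, config,
        scenario=scenario, silencing_factor=silencing_factor,
    )
    ns = SimpleNamespace(
        config=config, reference=reference, genotypes=genotypes,
        expression=expression, readset=readset,
        alignments=None, stats=None, pile=None, snps=None,
    )
    if align:
        ns.alignments, ns.stats = align_reads(readset, reference)
        ns.pile = pileup(ns.alignments, reference)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ns.snps, _ = build_list_a(genotypes)
    return ns
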