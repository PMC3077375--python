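import pytest

from hybridtrace.simulate import (
    HET_BOTH,
    HET_ONE_DONOR1,
    HET_ONE_DONOR2,
    HOM_HOM_DIFF,
    NON_DISCRIMINATING,
    SimulationConfig,
    coverage_for_depth,
)
from simutil import run_simulation


@pytest.fixture(scope="session")
def sim_small():
    """Mid-size balanced tetraploid simulation shared across test modules."""
    config = SimulationConfig(
        n_genes=10,
        transcript_length=400,
        snp_counts={
            HOM_HOM_DIFF: 10,
            HET_ONE_DONOR1: 10,
            HET_ONE_DONOR2: 5,
            HET_BOTH: 2,
            NON_DISCRIMINATING: 2,
        },
        coverage=coverage_for_depth(60, 36, 400),
        error_rate=0.005,
        seed=7,
    )
    return run_simulation(config)


@pytest.fixture(scope="session")
def sim_errorfree():
    """Small error-free simulation (every read is an exact haplotype substring)."""
    config = SimulationConfig(
        n_genes=6,
        transcript_length=300,
        snp_counts={
            HOM_HOM_DIFF: 6,
            HET_ONE_DONOR1: 4,
            HET_ONE_DONOR2: 4,
            HET_BOTH: 2,
            NON_DISCRIMINATING: 2,
        },
        coverage=coverage_for_depth(60, 36, 300),
        error_rate=0.0,
        seed=3,
    )
    return run_simulation(config)
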