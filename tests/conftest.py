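import numpy as np
import pytest

from ernakit.pipeline import run_pipeline
from ernakit.simulate import SimulationConfig, simulate_bundle

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic fixture: planted truth at study scale."""
    return simulate_bundle(SimulationConfig(), DEFAULT_SEED)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(
        bundle.peaks,
        bundle.genes,
        bundle.chrom_sizes,
        bundle.rnaseq_positions,
        bundle.rnaseq_condition,
    )


@pytest.fixture(scope="session")
def truth_by_id(bundle):
    return {r.region_id: r for r in bundle.truth}


def bitmap_union(intervals, size):
    """Per-base occupancy oracle for overlap/merge checks."""
    bits = np.zeros(size, dtype=bool)
    for iv in intervals:
        bits[iv.start : iv.end] = True
    return bits


def random_intervals(rng, n, size, max_len=2000, chrom="chrT"):
    from ernakit.core import GenomicInterval

    out = []
    for _ in range(n):
        start = int(rng.integers(0, size - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, size)))
    return out
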