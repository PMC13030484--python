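import pytest

from aavjunct.align import SeedExtendAligner
from aavjunct.refmodel import Genome, VectorModel, build_hybrid_reference
from aavjunct.simulate import (
    IntegrationTruth,
    plant_integration,
    simulate_host_genome,
    simulate_vector,
)


@pytest.fixture(scope="session")
def host_small() -> Genome:
    """Two-chromosome 10 kb host, enough for per-operation tests."""
    return simulate_host_genome(2, [6000, 4000], gc=0.45, seed=11)


@pytest.fixture(scope="session")
def vector() -> VectorModel:
    return simulate_vector(2928, 145, seed=11)


@pytest.fixture(scope="session")
def hybrid(host_small, vector):
    return build_hybrid_reference(host_small, vector)


@pytest.fixture(scope="session")
def aligner(hybrid) -> SeedExtendAligner:
    return SeedExtendAligner(hybrid, k=13, min_block=30)


@pytest.fixture(scope="session")
def planted(host_small, vector):
    """Clone with a full-length integration mid-chr1, plus its junctions."""
    truth = IntegrationTruth(
        clone_id="c1",
        chrom="chr1",
        pos1=3000,
        segments=(((0, len(vector)), "+"),),
    )
    clone, junctions = plant_integration(host_small, vector, truth, seed=11)
    return truth, clone, junctions
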