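import pytest

from introscope.pipeline import PipelineParams, analyze_trio
from introscope.simulate import SimConfig, simulate_all

# a 200-kbp trio that exercises every stage in a few seconds
TINY_KW = dict(
    seed=1,
    chrom_length=200_000,
    sv_count=4,
    gap_count=5,
    gap_length_range=(50, 300),
    introgression_long=(30_000, 170_000),
    introgression_short=(120_000, 126_000),
    contig_n50_target=50_000,
    line_unique_sv_count=3,
    sv_length_range=(50, 500),
)

TINY_PARAMS = PipelineParams(window_size=10_000, min_contig_length=40_000)


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig(**TINY_KW)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    """(dom, wild, genomes, contigs_by_line, truth) at 200 kbp."""
    return simulate_all(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_result(tiny_sim):
    dom, wild, genomes, contigs, truth = tiny_sim
    return analyze_trio(dom, wild, contigs, TINY_PARAMS)
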