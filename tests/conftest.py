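import numpy as np
import pytest

from regulome.model import FragmentSet, GenomeModel, GenomicInterval
from regulome import signal as sig
from regulome import simulate


@pytest.fixture(scope="session")
def genome():
    return simulate.make_genome(2, 1_000_000, 7)


@pytest.fixture(scope="session")
def annotation_truth(genome):
    return simulate.make_annotation(genome, seed=1)


@pytest.fixture(scope="session")
def annotation(annotation_truth):
    return annotation_truth[0]


@pytest.fixture(scope="session")
def truth(annotation_truth):
    return annotation_truth[1]


@pytest.fixture(scope="session")
def light_fragments(genome, truth):
    return simulate.simulate_fragments(genome, truth, "light", 200_000, 8.0, seed=1)


@pytest.fixture(scope="session")
def heavy_fragments(genome, truth):
    return simulate.simulate_fragments(genome, truth, "heavy", 200_000, 8.0, seed=2)


@pytest.fixture(scope="session")
def dns(genome, light_fragments, heavy_fragments):
    lw = sig.rpm_scale(sig.window_coverage(light_fragments, genome), len(light_fragments))
    hw = sig.rpm_scale(sig.window_coverage(heavy_fragments, genome), len(heavy_fragments))
    return sig.dns_track(lw, hw)


@pytest.fixture
def tiny_genome():
    return GenomeModel((("chr1", 5000),))


def random_fragments(rng, genome, n, max_len=120):
    ivs = []
    for _ in range(n):
        chrom, length = genome.chromosomes[rng.integers(len(genome.chromosomes))]
        flen = int(rng.integers(1, max_len))
        start = int(rng.integers(0, length - flen))
        ivs.append(GenomicInterval(chrom, start, start + flen, "."))
    return FragmentSet(ivs, "light", "rep1")
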