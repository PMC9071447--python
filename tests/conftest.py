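import numpy as np
import pytest

from axisislands.genome_model import Gene, GenomeAnnotation, GenomicInterval
from axisislands.island_calling import RegionPartition
from axisislands.signal_io import BinnedSignal, CoverageTrack


@pytest.fixture
def tiny_annotation():
    """chrI (10 kb): A[1000,2000)+, B[3000,4000)-, C[5000,6000)-; chrII empty."""
    return GenomeAnnotation(
        {"chrI": 10_000, "chrII": 4_000},
        [
            Gene("A", GenomicInterval("chrI", 1000, 2000, "+")),
            Gene("B", GenomicInterval("chrI", 3000, 4000, "-")),
            Gene("C", GenomicInterval("chrI", 5000, 6000, "-")),
        ],
    )


@pytest.fixture
def ramp_track():
    """chrI of 10 bp with values 0..9."""
    return CoverageTrack({"chrI": 10}, {"chrI": np.arange(10, dtype=float)})


@pytest.fixture
def two_region_partition():
    """chrI 10 kb: island [0,5000), desert [5000,10000)."""
    return RegionPartition(
        [
            (GenomicInterval("chrI", 0, 5000), "island"),
            (GenomicInterval("chrI", 5000, 10_000), "desert"),
        ],
        5000,
        1.75,
        1.0,
        {"chrI": 10_000},
    )


def make_binned(scores, bin_size=5000, chrom="chrI"):
    """BinnedSignal for a single chromosome from a flat score list."""
    scores = np.asarray(scores, dtype=float)
    L = bin_size * len(scores)
    intervals = [
        GenomicInterval(chrom, i * bin_size, (i + 1) * bin_size)
        for i in range(len(scores))
    ]
    return BinnedSignal(bin_size, intervals, scores, {chrom: L})
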