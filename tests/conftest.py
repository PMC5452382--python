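import pytest

from interset.regionio import Genome, GenomicInterval, RegionSet


@pytest.fixture
def toy_sets():
    """Three small, hand-checkable region sets on one chromosome."""
    a = RegionSet("A", (GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)))
    b = RegionSet("B", (GenomicInterval("chr1", 5, 15),))
    c = RegionSet("C", (GenomicInterval("chr1", 25, 40), GenomicInterval("chr1", 50, 60)))
    return [a, b, c]


@pytest.fixture
def small_genome():
    return Genome({"chr1": 1000, "chr2": 500})
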