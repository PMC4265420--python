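import numpy as np
import pytest

from crmine.genome import Genome
from crmine.intervals import AnnotationSet, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, size=50_000))
    return Genome({"chr1": seq})


@pytest.fixture
def empty_exons():
    return AnnotationSet([], kind="exon")


def make_intervals(spans, chrom="chr1"):
    return [GenomicInterval(chrom, s, e) for s, e in spans]
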