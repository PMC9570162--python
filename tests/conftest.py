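import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from contigplot.kmer_align import MatchSegment, Strand
from contigplot.seqio import SequenceRecord


def random_dna(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_segments(rng: np.random.Generator, n: int,
                    ref_length: int = 200, query_id: str = "q"
                    ) -> list[MatchSegment]:
    """Random, internally consistent match segments for tiling tests."""
    segs = []
    for _ in range(n):
        length = int(rng.integers(1, 40))
        rs = int(rng.integers(0, ref_length - length))
        qs = int(rng.integers(0, 1000))
        strand = Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
        segs.append(MatchSegment(query_id=query_id, ref_start=rs,
                                 ref_end=rs + length, query_start=qs,
                                 query_end=qs + length, strand=strand))
    return segs


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def small_reference():
    return SequenceRecord(id="ref", seq="ACGTACGT")
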