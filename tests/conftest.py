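import numpy as np
import pytest

from ssrmine.preprocess import GBSRead


def make_read(seq: str, read_id: str = "r1", q: int = 40,
              accession: str = "unassigned") -> GBSRead:
    return GBSRead(read_id=read_id, sequence=seq,
                   quality=tuple([q] * len(seq)), accession=accession)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
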