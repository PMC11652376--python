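import numpy as np
import pytest

from ribolens.corpus import GenicRegions, TranscriptRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_record(seq: str, tid: str = "t1") -> TranscriptRecord:
    """Record with a simple 25/50/25 region split."""
    n = len(seq)
    a, b = n // 4, 3 * n // 4
    return TranscriptRecord(tid, seq, GenicRegions((0, a), (a, b), (b, n)))


@pytest.fixture
def small_records(rng):
    return [make_record(random_rna(rng, 60), f"t{i}") for i in range(8)]
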