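import numpy as np
import pytest

from popgenflow.io import AlignedSequenceSet


def make_alignment(seqs, pops=None, ids=None, marker="test"):
    """Build an AlignedSequenceSet from sequence strings."""
    n = len(seqs)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    if pops is None:
        pops = ["P1"] * n
    mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    return AlignedSequenceSet(list(ids), dict(zip(ids, pops)), mat, marker)


@pytest.fixture
def tiny_alignment():
    """Three sequences, two segregating sites: the canonical worked example."""
    return make_alignment(["AAA", "AAT", "ATT"])


@pytest.fixture(scope="session")
def study_fixture():
    from popgenflow.simulate import make_paper_fixture

    return make_paper_fixture(seed=20260101)
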