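import numpy as np
import pytest

from mike.kmer_io import KmerParams, SortedKmerSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240321)


def make_set(codes, k, label="s", min_count=1):
    """SortedKmerSet from an unsorted iterable of integer codes."""
    arr = np.unique(np.asarray(sorted(set(int(c) for c in codes)), dtype=np.uint64))
    return SortedKmerSet(KmerParams(k=k, min_count=min_count), arr, label)


@pytest.fixture
def toy_params():
    return KmerParams(k=4, min_count=1)
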