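import pytest

from sof.readset import ReadSet

#: the five-read worked construction example
EXAMPLE_SEQS = ["AAGGG", "ACTTT", "AGGCT", "GCCAC", "TCCGC"]


def make_readset(seqs, prefix="r"):
    return ReadSet.from_sequences(
        [(f"{prefix}{i}", s) for i, s in enumerate(seqs, start=1)]
    )


@pytest.fixture
def example_reads():
    """The five example reads, in lexicographic (= file) order."""
    return make_readset(EXAMPLE_SEQS, prefix="S")


@pytest.fixture
def example_trie(example_reads):
    from sof.prefix_trie import build

    trie, _perm = build(example_reads, sort=True)
    return trie
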