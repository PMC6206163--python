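import numpy as np
import pytest

from enhwalk import SequenceRecord, write_fasta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_seq(rng):
    """Factory for i.i.d. uniform ACGT sequences."""

    def make(length=1500, gc=0.5):
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=length, p=p))

    return make


@pytest.fixture
def toy_genome(tmp_path, rng):
    """A two-chromosome ~70 kb random genome, written and indexable."""
    path = tmp_path / "toy_genome.fa"
    chroms = {
        "chr1": "".join(rng.choice(list("ACGT"), size=50_000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=20_000)),
    }
    write_fasta([SequenceRecord(name, seq) for name, seq in chroms.items()], path)
    return path, chroms
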