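import numpy as np
import pytest

import kpang


@pytest.fixture
def two_seq_collection():
    """The reverse-complement pair {S1=ATTG, S2=CAAT}."""
    return kpang.SequenceCollection.from_records(
        [("S1", "ATTG"), ("S2", "CAAT")]
    )


@pytest.fixture
def repeat_collection():
    """A single sequence with a same-strand tandem repeat (ATT twice)."""
    return kpang.SequenceCollection.from_records([("S1", "ATTATT")])


@pytest.fixture
def two_seq_index(two_seq_collection):
    text = kpang.concatenate(two_seq_collection)
    return kpang.build_kmer_index(text, 3), text


def random_collection(rng: np.random.Generator) -> kpang.SequenceCollection:
    """A randomized small haplotype collection mixing edit types."""
    cfg = kpang.SimulationConfig(
        n_haplotypes=int(rng.integers(2, 9)),
        length=int(rng.integers(20, 200)),
        substitution_rate=float(rng.choice([0.0, 0.02, 0.1])),
        indel_rate=float(rng.choice([0.0, 0.01])),
        inversion_rate=float(rng.choice([0.0, 1.0])),
        duplication_rate=float(rng.choice([0.0, 1.0])),
        inversion_length_range=(5, 20),
        duplication_length_range=(4, 15),
        seed=int(rng.integers(0, 2**31)),
    )
    collection, _ = kpang.generate_collection(cfg)
    return collection


@pytest.fixture
def fasta_file(tmp_path, two_seq_collection):
    path = tmp_path / "two.fa"
    with open(path, "w") as fh:
        for name, seq in two_seq_collection.records:
            fh.write(f">{name}\n{seq}\n")
    return path
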