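import numpy as np
import pytest

from atram.readsim import ReadSimParams, simulate_genome, simulate_paired_reads
from atram.seq_io import ReadPair, SequenceRecord
from atram.shard_db import build_database

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """A 40 kb genome with 4 genes, shared across read-level tests."""
    return simulate_genome(40_000, 4, seed=101)


@pytest.fixture(scope="session")
def small_library(small_genome):
    return simulate_paired_reads(
        small_genome,
        ReadSimParams(coverage=30, substitution_error_rate=0.0, seed=102),
    )


@pytest.fixture(scope="session")
def small_db(small_library):
    return build_database(small_library, n_shards=2)


def make_pairs(rng: np.random.Generator, n: int, read_len: int = 60) -> list[ReadPair]:
    pairs = []
    for i in range(n):
        pid = f"p{i:05d}"
        pairs.append(
            ReadPair(
                pair_id=pid,
                read1=SequenceRecord(id=pid + "/1", sequence=random_dna(rng, read_len)),
                read2=SequenceRecord(id=pid + "/2", sequence=random_dna(rng, read_len)),
            )
        )
    return pairs
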