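import numpy as np
import pytest

from atram.assembler import (
    AssemblyParams,
    assemble_reads,
    build_debruijn,
    extract_contigs,
    register_assembler,
)
from atram.search import reverse_complement
from atram.seq_io import SequenceRecord

from conftest import random_dna


def tile(source: str, read_len: int = 100, step: int = 5) -> list[SequenceRecord]:
    starts = list(range(0, len(source) - read_len + 1, step))
    if starts[-1] != len(source) - read_len:  # always cover the tail
        starts.append(len(source) - read_len)
    return [
        SequenceRecord(id=f"t{i}", sequence=source[s : s + read_len])
        for i, s in enumerate(starts)
    ]


def canonical(seq: str) -> str:
    return min(seq, reverse_complement(seq))


def test_build_debruijn_enumerates_kmers():
    params = AssemblyParams(k=15, min_kmer_count=1, min_contig_length=15)
    reads = [SequenceRecord(id="r", sequence="ACGGTAGCTTACCTAGA")]  # 17 bases
    graph = build_debruijn(reads, params)
    assert len(graph) == 3  # 17 - 15 + 1 distinct k-mers
    assert all(v == 1 for v in graph.values())


def test_build_debruijn_canonicalizes_reverse_complement():
    params = AssemblyParams(k=15, min_kmer_count=2, min_contig_length=15)
    rng = np.random.default_rng(1)
    seq = random_dna(rng, 40)
    reads = [
        SequenceRecord(id="f", sequence=seq),
        SequenceRecord(id="r", sequence=reverse_complement(seq)),
    ]
    graph = build_debruijn(reads, params)
    assert len(graph) == 40 - 15 + 1
    assert all(v == 2 for v in graph.values())


def test_build_debruijn_skips_non_acgt_and_short_reads(rng):
    from conftest import random_dna

    params = AssemblyParams(k=15, min_kmer_count=1, min_contig_length=15)
    left, right = random_dna(rng, 16), random_dna(rng, 16)
    reads = [
        SequenceRecord(id="n", sequence=left + "N" + right),
        SequenceRecord(id="short", sequence="ACGT"),
    ]
    graph = build_debruijn(reads, params)
    assert len(graph) == 4  # 2 windows per side of the N
    assert build_debruijn([reads[1]], params) == {}


def test_single_path_reconstruction(rng):
    source = random_dna(rng, 300)
    params = AssemblyParams(k=31, min_kmer_count=1, min_contig_length=100)
    graph = build_debruijn(tile(source), params)
    assert len(graph) == 300 - 31 + 1
    contigs = extract_contigs(graph, params)
    assert len(contigs) == 1
    assert contigs[0].sequence == canonical(source)
    assert contigs[0].contig_id == "c1"


def test_repeat_splits_assembly(rng):
    """An exact 40-base repeat at two loci branches the graph at k=31."""
    repeat = random_dna(rng, 40)
    source = (
        random_dna(rng, 300) + repeat + random_dna(rng, 300)
        + repeat + random_dna(rng, 300)
    )
    params = AssemblyParams(k=31, min_kmer_count=1, min_contig_length=100)
    contigs = assemble_reads(tile(source), params)
    assert len(contigs) > 1


def test_assemble_empty_and_too_short_reads():
    params = AssemblyParams()
    assert assemble_reads([], params) == []
    short = [SequenceRecord(id="s", sequence="ACGTACGT")]
    assert assemble_reads(short, params) == []


def test_orientation_invariance(rng):
    source = random_dna(rng, 500)
    params = AssemblyParams(k=31, min_kmer_count=1, min_contig_length=100)
    reads = tile(source)
    flipped = [
        SequenceRecord(id=r.id, sequence=reverse_complement(r.sequence))
        for r in reads
    ]
    c1 = assemble_reads(reads, params)
    c2 = assemble_reads(flipped, params)
    assert [c.sequence for c in c1] == [c.sequence for c in c2]


def test_determinism(rng):
    source = random_dna(rng, 800)
    params = AssemblyParams(k=31, min_kmer_count=1, min_contig_length=100)
    reads = tile(source)
    assert assemble_reads(reads, params) == assemble_reads(reads, params)


def test_weak_branch_trimming_removes_shared_error_bubble(rng):
    """Two reads sharing a substitution create a coverage-2 side path that
    must not split the high-coverage contig."""
    source = random_dna(rng, 600)
    reads = tile(source, step=3)  # ~33x
    reads += [reads[0], reads[-1]]  # reinforce the ends to k-mer depth >= 2
    err_pos = 300
    base = source[err_pos]
    alt = "A" if base != "A" else "C"
    mutated = source[:err_pos] + alt + source[err_pos + 1 :]
    for i in range(2):
        reads.append(
            SequenceRecord(id=f"e{i}", sequence=mutated[err_pos - 50 : err_pos + 50])
        )
    params = AssemblyParams(k=31, min_kmer_count=2, min_contig_length=100)
    contigs = assemble_reads(reads, params)
    assert len(contigs) == 1
    assert contigs[0].sequence == canonical(source)

    no_trim = AssemblyParams(k=31, min_kmer_count=2, min_contig_length=100,
                             weak_branch_ratio=0.0)
    assert len(assemble_reads(reads, no_trim)) > 1


def test_mean_kmer_coverage_reflects_depth(rng):
    source = random_dna(rng, 400)
    params = AssemblyParams(k=31, min_kmer_count=1, min_contig_length=100)
    contigs = assemble_reads(tile(source, step=10), params)  # 10x tiling
    assert len(contigs) == 1
    assert 5 <= contigs[0].mean_kmer_coverage <= 10


def test_plugin_backend_contract(rng):
    calls = []

    def fake(reads, params):
        calls.append(len(reads))
        return []

    register_assembler("fake", fake)
    assert assemble_reads(tile(random_dna(rng, 200)), AssemblyParams(),
                          backend="plugin:fake") == []
    assert calls
    with pytest.raises(ValueError):
        assemble_reads([], AssemblyParams(), backend="nope")


@pytest.mark.parametrize("k,mkc", [(14, 1), (16, 1), (31, 0)])
def test_invalid_params_rejected(k, mkc):
    with pytest.raises(ValueError):
        AssemblyParams(k=k, min_kmer_count=mkc)


def test_reconstruction_property_random_lengths(rng):
    """Error-free tiling reads of repeat-free sources reassemble exactly."""
    params = AssemblyParams(k=31, min_kmer_count=1, min_contig_length=100)
    for _ in range(10):
        n = int(rng.integers(500, 3001))
        source = random_dna(rng, n)
        kmers = {source[i : i + 31] for i in range(n - 30)}
        if len(kmers) != n - 30:  # exact repeat at k: skip (vanishingly rare)
            continue
        contigs = assemble_reads(tile(source), params)
        assert len(contigs) == 1
        assert contigs[0].sequence == canonical(source)
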