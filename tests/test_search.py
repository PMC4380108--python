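import numpy as np
import pytest
from Bio import Align

from atram.search import (
    ScoringScheme,
    SearchParams,
    gather_read_pool,
    local_alignments,
    reverse_complement,
    search_shard,
    seed_and_extend,
    translate_six_frames,
)
from atram.seq_io import ReadPair, SequenceRecord
from atram.shard_db import build_database

from conftest import make_pairs, random_dna


def sw_oracle(scheme: ScoringScheme):
    """Independent full Smith-Waterman scorer (biopython)."""
    al = Align.PairwiseAligner(mode="local")
    if scheme.mode == "dna":
        al.match_score = scheme.match
        al.mismatch_score = scheme.mismatch
    else:
        from Bio.Align import substitution_matrices

        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = scheme.gap_open + scheme.gap_extend
    al.extend_gap_score = scheme.gap_extend
    return al


@pytest.mark.parametrize(
    "dna, frame, expected",
    [
        ("ATGAAATGA", 0, "MK*"),
        ("TCATTTCAT", 3, "MK*"),  # revcomp is ATGAAATGA
        ("ATGA", 1, "*"),  # offset 1 leaves one codon TGA
        ("ATGA", 2, ""),
    ],
)
def test_translate_six_frames(dna, frame, expected):
    assert translate_six_frames(dna)[frame] == expected


def test_translate_reverse_frames_mirror_forward():
    rng = np.random.default_rng(3)
    dna = random_dna(rng, 60)
    fwd = translate_six_frames(dna)
    rev = translate_six_frames(reverse_complement(dna))
    assert fwd[3:] == rev[:3]


def test_seed_and_extend_exact_substring():
    rng = np.random.default_rng(4)
    subject = random_dna(rng, 100)
    query = subject[30:62]
    a = seed_and_extend(query, subject, ScoringScheme.dna(), 12)
    assert a.score == 5 * len(query)
    assert a.query_span == (0, len(query))
    assert a.subject_span == (30, 62)


def test_seed_and_extend_identical_sequences():
    rng = np.random.default_rng(5)
    s = random_dna(rng, 80)
    a = seed_and_extend(s, s, ScoringScheme.dna(), 12)
    assert a.score == 5 * 80
    assert a.query_span == (0, 80) and a.subject_span == (0, 80)


def test_seed_and_extend_no_seed_returns_none():
    assert seed_and_extend("A" * 30, "C" * 50, ScoringScheme.dna(), 12) is None


def test_seed_and_extend_never_beats_full_smith_waterman():
    """Seeded trials: our score <= SW optimum always; equal in >= 95% of
    hit-returning cases (the X-drop can only truncate)."""
    rng = np.random.default_rng(6)
    scheme = ScoringScheme.dna()
    oracle = sw_oracle(scheme)
    returned = equal = 0
    for _ in range(200):
        n1 = int(rng.integers(50, 151))
        n2 = int(rng.integers(50, 151))
        query = random_dna(rng, n1)
        subject = random_dna(rng, n2)
        if rng.random() < 0.5:  # plant homology so seeds exist
            k = int(rng.integers(20, min(n1, n2)))
            pos_q = int(rng.integers(0, n1 - k + 1))
            pos_s = int(rng.integers(0, n2 - k + 1))
            subject = subject[:pos_s] + query[pos_q : pos_q + k] + subject[pos_s + k :]
        a = seed_and_extend(query, subject, scheme, 12)
        if a is None:
            continue
        opt = oracle.score(query, subject)
        assert a.score <= opt
        returned += 1
        equal += a.score == opt
    assert returned >= 50
    assert equal / returned >= 0.95


def _planted_shard(rng, n_random=90, n_planted=10, query_len=300):
    query = random_dna(rng, query_len)
    pairs = make_pairs(rng, n_random, read_len=100)
    planted_ids = []
    for i in range(n_planted):
        pos = int(rng.integers(0, query_len - 100 + 1))
        seq = query[pos : pos + 100]
        if i % 2:
            seq = reverse_complement(seq)
        pid = f"planted{i:02d}"
        planted_ids.append(pid)
        pairs.append(
            ReadPair(
                pair_id=pid,
                read1=SequenceRecord(id=pid + "/1", sequence=seq),
                read2=SequenceRecord(id=pid + "/2", sequence=random_dna(rng, 100)),
            )
        )
    db = build_database(pairs, n_shards=1)
    return query, db, planted_ids


def test_search_shard_finds_planted_reads_both_strands(rng):
    query, db, planted = _planted_shard(rng)
    hits = search_shard(
        SequenceRecord(id="q", sequence=query), db.shard(0),
        ScoringScheme.dna(), SearchParams(),
    )
    by_id = {h.pair_id: h for h in hits}
    assert set(planted) <= set(by_id)
    for i, pid in enumerate(planted):
        assert by_id[pid].score == 500
        assert by_id[pid].strand == ("-" if i % 2 else "+")
        assert by_id[pid].read_span == (0, 100)


def test_search_shard_reverse_complement_query_swaps_strands(rng):
    query, db, planted = _planted_shard(rng)
    params = SearchParams()
    fwd = search_shard(SequenceRecord(id="q", sequence=query), db.shard(0),
                       ScoringScheme.dna(), params)
    rev = search_shard(
        SequenceRecord(id="q", sequence=reverse_complement(query)),
        db.shard(0), ScoringScheme.dna(), params,
    )
    f = {h.pair_id: h for h in fwd}
    r = {h.pair_id: h for h in rev}
    assert set(f) == set(r)
    for pid in f:
        assert f[pid].score == r[pid].score
        assert f[pid].strand != r[pid].strand


def test_search_shard_monotonic_in_min_score_and_top_n(rng):
    query, db, _ = _planted_shard(rng)
    q = SequenceRecord(id="q", sequence=query)
    scheme = ScoringScheme.dna()
    loose = search_shard(q, db.shard(0), scheme, SearchParams(min_score=40))
    strict = search_shard(q, db.shard(0), scheme, SearchParams(min_score=300))
    assert {h.pair_id for h in strict} <= {h.pair_id for h in loose}
    top3 = search_shard(q, db.shard(0), scheme, SearchParams(top_n_per_shard=3))
    assert [h.pair_id for h in top3] == [h.pair_id for h in loose[:3]]


def test_search_shard_rejects_protein_query_in_dna_mode(rng):
    _, db, _ = _planted_shard(rng)
    with pytest.raises(ValueError, match="protein"):
        search_shard(SequenceRecord(id="q", sequence="MKLVPEF" * 10),
                     db.shard(0), ScoringScheme.dna(), SearchParams())


def test_protein_search_finds_coding_read(rng):
    protein = "M" + "".join(
        "ARNDCQEGHILKMFPSTWYV"[i] for i in rng.integers(0, 20, 99)
    )
    # reverse-translate with a fixed codon choice, then embed in a read
    codon = {aa: None for aa in set(protein)}
    from Bio.Data.CodonTable import standard_dna_table

    for c, aa in standard_dna_table.forward_table.items():
        if aa in codon and codon[aa] is None:
            codon[aa] = c
    cds = "".join(codon[aa] for aa in protein)
    read1 = cds[30:130]
    pairs = make_pairs(rng, 50, read_len=100)
    pairs.append(ReadPair(
        pair_id="coding",
        read1=SequenceRecord(id="coding/1", sequence=read1),
        read2=SequenceRecord(id="coding/2", sequence=random_dna(rng, 100)),
    ))
    db = build_database(pairs, n_shards=1)
    hits = search_shard(
        SequenceRecord(id="prot", sequence=protein), db.shard(0),
        ScoringScheme.protein(), SearchParams(),
    )
    assert hits and hits[0].pair_id == "coding"
    span = hits[0].read_span
    assert 0 <= span[0] < span[1] <= 100
    assert (span[1] - span[0]) % 3 == 0  # whole codons on the read


def test_gather_read_pool_dedup_and_fraction(rng):
    query, db, planted = _planted_shard(rng)
    q1 = SequenceRecord(id="q1", sequence=query)
    q2 = SequenceRecord(id="q2", sequence=query[:200])
    pool = gather_read_pool(db, [q1, q2], ScoringScheme.dna(), SearchParams())
    ids = [p.pair_id for p in pool]
    assert len(ids) == len(set(ids))
    assert set(planted) <= set(ids)


def test_gather_read_pool_fraction_restricts_shards(rng):
    pairs = make_pairs(rng, 40, read_len=100)
    query = pairs[0].read1.sequence
    db = build_database(pairs, n_shards=2)
    target_shard = next(
        s.index for s in db.shards if pairs[0].pair_id in s.mate_store
    )
    pool_all = gather_read_pool(
        db, [SequenceRecord(id="q", sequence=query)],
        ScoringScheme.dna(), SearchParams(fraction=1.0),
    )
    assert pairs[0].pair_id in {p.pair_id for p in pool_all}
    pool_half = gather_read_pool(
        db, [SequenceRecord(id="q", sequence=query)],
        ScoringScheme.dna(), SearchParams(fraction=0.5),
    )
    if target_shard == 1:
        assert pairs[0].pair_id not in {p.pair_id for p in pool_half}


def test_local_alignments_reports_separated_blocks(rng):
    """A subject made of two query blocks separated by unrelated sequence
    yields two alignments whose union spans both blocks."""
    query = random_dna(rng, 400)
    subject = query[:150] + random_dna(rng, 300) + query[250:]
    alns = local_alignments(query, subject, ScoringScheme.dna(), 28, min_score=40)
    spans = sorted(a.query_span for a in alns)
    assert len(alns) >= 2
    assert spans[0][0] == 0 and spans[-1][1] == 400
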