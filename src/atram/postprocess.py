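"""Validation metrics: percent coverage, uncorrected p-distance, orthology.

A contig is validated three ways, mirroring how targeted assemblies are
vetted in phylogenomics: how much of the reference it covers, how far it has
diverged (uncorrected p-distance: the raw proportion of differing sites, no
substitution-model correction), and whether it is the reciprocal best hit of
its own query gene in the whole reference protein set.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _align
from .assembler import Contig
from .search import (
    ScoringScheme,
    build_seed_words,
    _extend_clusters,
    _seed_diagonals,
    reverse_complement,
    translate_six_frames,
)
from .seq_io import SequenceRecord

__all__ = [
    "AlignedPair",
    "OrthologyCall",
    "semi_global_align",
    "p_distance",
    "percent_coverage",
    "reciprocal_best_hit",
]

_DNA_UNAMBIG = frozenset("ACGT")

# Gap cost for unaligned contig bases when aligning a genomic contig to a
# spliced (exon-only) reference: introns are expected, so extending this gap
# is cheap; the open cost still keeps unrelated sequence from fragmenting.
INTRON_GAP = (-12, -1)
_PROT_UNAMBIG = frozenset("ARNDCQEGHILKMFPSTWYV")


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped sequences plus site counts.

    Comparable sites are columns where both sequences carry an unambiguous
    symbol (gaps, N and ambiguity codes excluded on either side).
    """

    seq_a: str
    seq_b: str
    score: int
    comparable_sites: int
    differing_sites: int


@dataclass(frozen=True)
class OrthologyCall:
    contig_id: str
    query_gene_id: str
    best_reference_hit: str
    best_score: int
    is_ortholog: bool


def _count_sites(seq_a: str, seq_b: str, mode: str) -> tuple[int, int]:
    ok = _DNA_UNAMBIG if mode == "dna" else _PROT_UNAMBIG
    comparable = differing = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca in ok and cb in ok:
            comparable += 1
            if ca != cb:
                differing += 1
    return comparable, differing


def make_aligned_pair(seq_a: str, seq_b: str, score: int = 0,
                      mode: str = "dna") -> AlignedPair:
    """Build an :class:`AlignedPair` from already-gapped sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("gapped sequences must have equal length")
    comparable, differing = _count_sites(seq_a, seq_b, mode)
    return AlignedPair(seq_a, seq_b, score, comparable, differing)


def semi_global_align(
    a: str,
    b: str,
    scheme: ScoringScheme,
    insertion_gap: tuple[int, int] | None = None,
) -> AlignedPair:
    """Optimal overlap alignment (free end gaps on both sequences).

    Traceback ties are resolved deterministically, preferring an aligned
    column over a gap in ``a`` over a gap in ``b``. ``insertion_gap`` gives a
    separate (open, extend) cost for gaps in ``b`` — bases of ``a`` left
    unaligned, e.g. introns when ``a`` is a genomic contig and ``b`` a
    spliced reference; by default both gap types use the scheme's costs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    go_f, ge_f = insertion_gap if insertion_gap else (scheme.gap_open, scheme.gap_extend)
    a_codes = scheme.encode(a)
    b_codes = scheme.encode(b)
    score, ei, ej, state, PM, PE, PF = _align.overlap_fill(
        a_codes, b_codes, scheme.matrix(),
        scheme.gap_open, scheme.gap_extend, go_f, ge_f,
    )
    cols_a: list[str] = []
    cols_b: list[str] = []
    # trailing overhangs (free end gaps)
    for j in range(len(b) - 1, ej - 1, -1):
        cols_a.append("-")
        cols_b.append(b[j])
    for i in range(len(a) - 1, ei - 1, -1):
        cols_a.append(a[i])
        cols_b.append("-")
    i, j = ei, ej
    while state != 3 and i >= 0 and j >= 0:
        if state == 0:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            state = int(PM[i, j])
            i -= 1
            j -= 1
        elif state == 1:  # gap in a, consumes b
            cols_a.append("-")
            cols_b.append(b[j - 1])
            state = int(PE[i, j])
            j -= 1
        else:  # gap in b, consumes a
            cols_a.append(a[i - 1])
            cols_b.append("-")
            state = int(PF[i, j])
            i -= 1
    # leading overhangs
    for jj in range(j - 1, -1, -1):
        cols_a.append("-")
        cols_b.append(b[jj])
    for ii in range(i - 1, -1, -1):
        cols_a.append(a[ii])
        cols_b.append("-")
    seq_a = "".join(reversed(cols_a))
    seq_b = "".join(reversed(cols_b))
    return make_aligned_pair(seq_a, seq_b, int(score), scheme.mode)


def p_distance(pair: AlignedPair) -> float | None:
    """Proportion of differing sites among comparable (non-gap) sites.

    ``None`` (missing) when the alignment has no comparable sites.
    """
    if pair.comparable_sites == 0:
        return None
    return pair.differing_sites / pair.comparable_sites


def percent_coverage(
    contig: Contig | SequenceRecord,
    reference: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> float:
    """Fraction of reference positions covered by aligned contig symbols.

    The contig is tried in both orientations; the better-scoring one counts
    (ties prefer forward).
    """
    scheme = scheme or ScoringScheme.dna()
    seq = contig.sequence
    best = semi_global_align(seq, reference.sequence, scheme, INTRON_GAP)
    rc = semi_global_align(reverse_complement(seq), reference.sequence, scheme, INTRON_GAP)
    pair = rc if rc.score > best.score else best
    covered = sum(
        1 for ca, cb in zip(pair.seq_a, pair.seq_b) if ca != "-" and cb != "-"
    )
    return covered / len(reference.sequence)


def best_metric_alignment(
    contig: Contig | SequenceRecord,
    reference: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> AlignedPair:
    """The orientation-resolved overlap alignment used by the metrics."""
    scheme = scheme or ScoringScheme.dna()
    seq = contig.sequence
    best = semi_global_align(seq, reference.sequence, scheme, INTRON_GAP)
    rc = semi_global_align(reverse_complement(seq), reference.sequence, scheme, INTRON_GAP)
    return rc if rc.score > best.score else best


def reciprocal_best_hit(
    contig: Contig,
    query_gene_id: str,
    reference_proteome: list[SequenceRecord],
    scheme: ScoringScheme | None = None,
    seed_length: int = 4,
    band: int = 16,
) -> OrthologyCall:
    """Reciprocal best-hit orthology test against a whole protein set.

    The contig's six translated frames are searched against every reference
    protein; the assembly is called orthologous iff the gene that produced
    the query is the single best hit (score ties broken by id ascending).
    """
    scheme = scheme or ScoringScheme.protein()
    if scheme.mode != "protein":
        raise ValueError("reciprocal_best_hit requires a protein scoring scheme")
    if not any(p.id == query_gene_id for p in reference_proteome):
        raise ValueError(f"gene {query_gene_id!r} absent from the reference proteome")
    frames = [f for f in translate_six_frames(contig.sequence) if len(f) >= seed_length]
    frame_words = [(f, build_seed_words(f, seed_length), scheme.encode(f)) for f in frames]
    best_id = ""
    best_score = -1
    for prot in sorted(reference_proteome, key=lambda p: p.id):
        prot_best = 0
        for frame, words, codes in frame_words:
            clusters = _seed_diagonals(words, prot.sequence, seed_length)
            if not clusters:
                continue
            alns = _extend_clusters(codes, prot.sequence, scheme, clusters,
                                    seed_length, band)
            if alns:
                prot_best = max(prot_best, max(a.score for a in alns))
        if prot_best > best_score:
            best_score = prot_best
            best_id = prot.id
    return OrthologyCall(
        contig_id=contig.contig_id,
        query_gene_id=query_gene_id,
        best_reference_hit=best_id,
        best_score=best_score,
        is_ortholog=best_id == query_gene_id,
    )
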