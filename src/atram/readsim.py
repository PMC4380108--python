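"""Simulated genomes, diverged homologs and paired-end read libraries.

The generator stands in for a real insect-scale reference plus resequencing
run at desk scale: a uniform-random background genome carrying non-overlapping
intron-bearing protein-coding genes, a homolog generator that applies i.i.d.
nucleotide substitutions (no indels, so reading frames and coordinates are
preserved), and a paired-end read simulator with normally distributed insert
sizes and an i.i.d. substitution error model. Everything is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .search import reverse_complement
from .seq_io import ReadPair, SequenceRecord

__all__ = [
    "Gene",
    "SimulatedGenome",
    "ReadSimParams",
    "simulate_genome",
    "mutate_homolog",
    "simulate_paired_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# the 61 sense codons of the standard code
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    exons: tuple[tuple[int, int], ...]  # genome coords, 0-based half-open, ordered
    strand: str  # '+' or '-'

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class SimulatedGenome:
    sequence: str
    genes: tuple[Gene, ...]
    seed: int

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def coding_sequence(self, gene_id: str) -> SequenceRecord:
        """Spliced coding DNA in coding orientation."""
        g = self.gene(gene_id)
        seq = "".join(self.sequence[s:e] for s, e in g.exons)
        if g.strand == "-":
            seq = reverse_complement(seq)
        return SequenceRecord(id=gene_id, sequence=seq)

    def protein(self, gene_id: str) -> SequenceRecord:
        cds = self.coding_sequence(gene_id)
        return SequenceRecord(
            id=gene_id, sequence=str(Seq(cds.sequence).translate())
        )


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    coverage: float = 30.0
    substitution_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def simulate_genome(
    length: int,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (2, 4),
    seed: int = 0,
    exon_codons: tuple[int, int] = (50, 100),
    intron_length: tuple[int, int] = (50, 500),
    flank: int = 500,
) -> SimulatedGenome:
    """Random genome with non-overlapping, intron-bearing coding genes.

    Exons are built from sense codons only (so each spliced gene translates
    without internal stops) with lengths of ``exon_codons`` codons; introns
    and intergenic background are uniform random DNA. Genes keep at least
    ``flank`` bases of background on each side and may sit on either strand.
    """
    rng = np.random.default_rng(seed)
    structures = []
    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exon_lens = [3 * int(rng.integers(*exon_codons)) for _ in range(n_ex)]
        intron_lens = [
            int(rng.integers(intron_length[0], intron_length[1] + 1))
            for _ in range(n_ex - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        structures.append((exon_lens, intron_lens, strand))

    spans = [sum(el) + sum(il) for el, il, _ in structures]
    required = sum(spans) + flank * (n_genes + 1)
    if required > length:
        raise ValueError(
            f"genome of {length} bases cannot hold {n_genes} genes "
            f"(needs >= {required})"
        )
    slack = length - required
    # spread the slack over the n_genes+1 gaps, deterministically random
    if n_genes > 0:
        extra = rng.multinomial(slack, [1 / (n_genes + 1)] * (n_genes + 1))
    else:
        extra = [slack]

    chunks: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for gi, (exon_lens, intron_lens, strand) in enumerate(structures):
        gap = flank + int(extra[gi])
        chunks.append(_random_dna(rng, gap))
        pos += gap
        # coding sequence laid down exon by exon, in genome orientation
        cds = _random_cds(rng, sum(exon_lens) // 3)
        if strand == "-":
            laid = reverse_complement(cds)
            laid_lens = exon_lens[::-1]
        else:
            laid = cds
            laid_lens = exon_lens
        exons = []
        off = 0
        for ei, el in enumerate(laid_lens):
            chunks.append(laid[off : off + el])
            exons.append((pos, pos + el))
            pos += el
            off += el
            if ei < len(laid_lens) - 1:
                il = intron_lens[ei]
                chunks.append(_random_dna(rng, il))
                pos += il
        genes.append(Gene(gene_id=f"gene{gi + 1:03d}", exons=tuple(exons), strand=strand))
    tail = flank + int(extra[-1]) if n_genes > 0 else length
    chunks.append(_random_dna(rng, tail))
    sequence = "".join(chunks)
    assert len(sequence) == length
    return SimulatedGenome(sequence=sequence, genes=tuple(genes), seed=seed)


def mutate_homolog(
    genome: SimulatedGenome, nt_divergence: float, seed: int = 0
) -> SimulatedGenome:
    """Substitute each position independently with probability ``nt_divergence``.

    Substitutions go to a uniformly random *different* base; no indels, so
    gene coordinates carry over unchanged.
    """
    if not 0 <= nt_divergence < 0.75:
        raise ValueError("nt_divergence must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    code = np.zeros(128, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    idx = code[arr]
    mask = rng.random(len(arr)) < nt_divergence
    shift = rng.integers(1, 4, size=int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    return SimulatedGenome(
        sequence=_BASES[idx].tobytes().decode("ascii"),
        genes=genome.genes,
        seed=seed,
    )


def simulate_paired_reads(
    genome: SimulatedGenome, params: ReadSimParams
) -> list[ReadPair]:
    """Paired-end reads at the requested coverage.

    Fragment lengths ~ Normal(insert_mean, insert_sd) truncated to
    [read_length, genome length]; starts uniform; each fragment is sequenced
    from a uniformly random strand (as in a real library). Read 1 is the
    fragment's 5' end on the sequenced strand, read 2 the reverse complement
    of its 3' end; substitution errors are i.i.d. per base.
    ``n_pairs = round(coverage * L / (2 * read_length))``.
    """
    rng = np.random.default_rng(params.seed)
    L = len(genome.sequence)
    rl = params.read_length
    if rl > L:
        raise ValueError("read_length exceeds genome length")
    n_pairs = round(params.coverage * L / (2 * rl))
    frags = np.clip(
        np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)),
        rl,
        L,
    ).astype(np.int64)
    starts = (rng.random(n_pairs) * (L - frags + 1)).astype(np.int64)
    flip = rng.random(n_pairs) < 0.5

    code = np.zeros(128, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    gidx = code[np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)]

    pairs: list[ReadPair] = []
    err = params.substitution_error_rate
    for i in range(n_pairs):
        s = int(starts[i])
        f = int(frags[i])
        if flip[i]:  # fragment sequenced from the reverse strand
            r1 = 3 - gidx[s + f - rl : s + f][::-1]
            r2 = gidx[s : s + rl].copy()
        else:
            r1 = gidx[s : s + rl].copy()
            r2 = 3 - gidx[s + f - rl : s + f][::-1]
        if err > 0:
            for r in (r1, r2):
                m = rng.random(rl) < err
                ne = int(m.sum())
                if ne:
                    r[m] = (r[m] + rng.integers(1, 4, size=ne)) % 4
        pid = f"frag{i:07d}"
        pairs.append(
            ReadPair(
                pair_id=pid,
                read1=SequenceRecord(id=pid + "/1",
                                     sequence=_BASES[r1].tobytes().decode("ascii")),
                read2=SequenceRecord(id=pid + "/2",
                                     sequence=_BASES[r2].tobytes().decode("ascii")),
            )
        )
    return pairs
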