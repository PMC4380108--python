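"""Built-in de Bruijn graph assembler for locus-restricted read pools.

Nodes are canonical k-mers (lexicographic min of a k-mer and its reverse
complement) counted over both mates and both strands; contigs are maximal
non-branching paths (unitigs). Error removal is deliberately minimal — the
pools this assembler sees are small and restricted to one locus:

* k-mers below ``min_kmer_count`` are dropped (sequencing-error singletons);
* at each branch, children whose count is at most ``weak_branch_ratio`` times
  their strongest sibling are dropped. This removes the coverage-2 bubble
  paths that two reads sharing an error create at 30-50x depth, while a
  genuine repeat branch (balanced coverage) still splits the contig. On
  error-free input no branches exist and the filter is a no-op.

Heavier machinery (scaffolding, full bubble popping) belongs to plugin
assemblers, which only need to honor the ``assemble_reads`` signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .search import reverse_complement
from .seq_io import SequenceRecord

__all__ = [
    "AssemblyParams",
    "Contig",
    "build_debruijn",
    "extract_contigs",
    "assemble_reads",
    "register_assembler",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class AssemblyParams:
    k: int = 31
    min_kmer_count: int = 2
    min_contig_length: int = 100
    weak_branch_ratio: float = 0.2

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be an odd integer >= 15")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")
        if not 0 <= self.weak_branch_ratio < 1:
            raise ValueError("weak_branch_ratio must be in [0, 1)")


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    mean_kmer_coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    def canonical(self) -> str:
        rc = reverse_complement(self.sequence)
        return min(self.sequence, rc)


def _canon(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return rc if rc < kmer else kmer


def build_debruijn(
    reads: Sequence[SequenceRecord], params: AssemblyParams
) -> dict[str, int]:
    """Canonical k-mer -> count, after abundance and weak-branch filtering.

    k-mers containing non-ACGT symbols are skipped. Reads shorter than k
    contribute nothing; if every read is, the graph is empty.
    """
    k = params.k
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if any(c not in _BASES for c in km):
                continue
            km = _canon(km)
            counts[km] = counts.get(km, 0) + 1
    if params.min_kmer_count > 1:
        counts = {km: c for km, c in counts.items() if c >= params.min_kmer_count}
    if params.weak_branch_ratio > 0:
        _trim_weak_branches(counts, params.weak_branch_ratio)
    return counts


def _successors(counts: dict[str, int], kmer: str) -> list[str]:
    """Oriented successors of an oriented k-mer (as oriented strings)."""
    suffix = kmer[1:]
    out = []
    for b in _BASES:
        nxt = suffix + b
        if _canon(nxt) in counts:
            out.append(nxt)
    return out


def _predecessors(counts: dict[str, int], kmer: str) -> list[str]:
    prefix = kmer[:-1]
    out = []
    for b in _BASES:
        prv = b + prefix
        if _canon(prv) in counts:
            out.append(prv)
    return out


def _trim_weak_branches(counts: dict[str, int], ratio: float) -> None:
    """Drop branch children dominated by a much deeper sibling (in place)."""
    doomed: set[str] = set()
    for km in counts:
        for oriented in (km, reverse_complement(km)):
            succ = _successors(counts, oriented)
            if len(succ) < 2:
                continue
            cmax = max(counts[_canon(s)] for s in succ)
            for s in succ:
                if counts[_canon(s)] <= ratio * cmax:
                    doomed.add(_canon(s))
    for km in doomed:
        counts.pop(km, None)


def extract_contigs(counts: dict[str, int], params: AssemblyParams) -> list[Contig]:
    """Emit maximal non-branching paths as contigs in canonical orientation.

    Deterministic: contigs are ranked by descending length, ties by sequence,
    and named ``c1, c2, ...``. Mean coverage is the mean count of the path's
    k-mers.
    """
    if not counts:
        return []

    def is_path_start(oriented: str) -> bool:
        preds = _predecessors(counts, oriented)
        if len(preds) != 1:
            return True
        return len(_successors(counts, preds[0])) != 1

    emitted: set[str] = set()  # canonical first k-mer of emitted paths
    raw: list[tuple[str, float]] = []

    def walk(start: str) -> tuple[str, float]:
        path = [start]
        seen = {_canon(start)}
        cur = start
        while True:
            succ = _successors(counts, cur)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(_predecessors(counts, nxt)) != 1:
                break
            if _canon(nxt) in seen:  # closed a cycle
                break
            path.append(nxt)
            seen.add(_canon(nxt))
            cur = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(counts[_canon(p)] for p in path) / len(path)
        return seq, cov

    visited: set[str] = set()
    for km in sorted(counts):  # sorted for determinism
        for oriented in (km, reverse_complement(km)):
            if km in visited or not is_path_start(oriented):
                continue
            seq, cov = walk(oriented)
            canon_seq = min(seq, reverse_complement(seq))
            if canon_seq not in emitted:
                emitted.add(canon_seq)
                raw.append((canon_seq, cov))
            for i in range(len(seq) - params.k + 1):
                visited.add(_canon(seq[i : i + params.k]))

    # isolated cycles: every node has in/out degree 1, no path start found
    for km in sorted(counts):
        if km in visited:
            continue
        seq, cov = walk(km)
        canon_seq = min(seq, reverse_complement(seq))
        if canon_seq not in emitted:
            emitted.add(canon_seq)
            raw.append((canon_seq, cov))
        for i in range(len(seq) - params.k + 1):
            visited.add(_canon(seq[i : i + params.k]))

    raw = [(s, c) for s, c in raw if len(s) >= params.min_contig_length]
    raw.sort(key=lambda sc: (-len(sc[0]), sc[0]))
    return [
        Contig(contig_id=f"c{i + 1}", sequence=s, mean_kmer_coverage=round(c, 3))
        for i, (s, c) in enumerate(raw)
    ]


_PLUGINS: dict[str, Callable[[Sequence[SequenceRecord], AssemblyParams], list[Contig]]] = {}


def register_assembler(name: str, fn) -> None:
    """Register a plugin backend with the ``assemble_reads`` contract:
    same signature, deterministic given its seed."""
    _PLUGINS[name] = fn


def assemble_reads(
    reads: Sequence[SequenceRecord],
    params: AssemblyParams,
    backend: str = "internal",
) -> list[Contig]:
    if backend == "internal":
        return extract_contigs(build_debruijn(reads, params), params)
    if backend.startswith("plugin:"):
        backend = backend.split(":", 1)[1]
    if backend in _PLUGINS:
        return _PLUGINS[backend](reads, params)
    raise ValueError(f"unknown assembler backend {backend!r}")
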