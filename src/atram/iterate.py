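"""The iterative target-restricted assembly loop.

Iteration 0 searches the read database with the user's query (DNA or
protein); every later iteration searches with the previous iteration's kept
contigs (always DNA — contigs are nucleotide, and from here on matching reads
are identical, not merely similar, to the growing assembly). After each
assembly the contigs are scored against the ORIGINAL target — never against
intermediate contigs — which anchors the walk and prevents drift. The loop
stops at the first of: no hits / no kept contigs, contig-set convergence,
autocomplete (a contig reaches both ends of the query), or the iteration cap.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .assembler import AssemblyParams, Contig, assemble_reads
from .search import (
    Alignment,
    ScoringScheme,
    SearchParams,
    gather_read_pool,
    local_alignments,
    translate_six_frames,
    reverse_complement,
)
from .seq_io import SequenceRecord
from .shard_db import ShardedDatabase

__all__ = [
    "AtramParams",
    "IterationRecord",
    "AtramResult",
    "score_contigs_vs_target",
    "check_autocomplete",
    "converged",
    "run_atram",
]

Status = Literal["continue", "converged", "autocomplete", "max_iterations", "no_hits"]


@dataclass(frozen=True)
class AtramParams:
    max_iterations: int = 5
    fraction: float = 1.0
    autocomplete: bool = False
    search: SearchParams = field(default_factory=SearchParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    keep_top_contigs: int = 5
    contig_min_score: int = 70
    end_window_fraction: float = 0.05
    assembler_backend: str = "internal"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.end_window_fraction <= 0.5:
            raise ValueError("end_window_fraction must be in (0, 0.5]")


@dataclass
class IterationRecord:
    iteration: int
    n_hits: int
    n_pairs_in_pool: int
    contigs: list[Contig]
    kept_contigs: list[Contig]
    kept_scores: list[int]
    status: Status


@dataclass
class AtramResult:
    target_id: str
    final_contigs: list[Contig]
    best_contig: Contig | None
    trace: list[IterationRecord]
    termination: Status


_PROTEIN_ONLY = set("EFILPQZ*")  # residues that cannot appear in IUPAC DNA


def looks_like_protein(seq: str) -> bool:
    return bool(set(seq.upper()) & _PROTEIN_ONLY)


def _target_scheme(target: SequenceRecord, mode: str) -> ScoringScheme:
    if mode == "protein" or (mode == "auto" and looks_like_protein(target.sequence)):
        return ScoringScheme.protein()
    return ScoringScheme.dna()


def _contig_alignments(
    contig: Contig,
    target: SequenceRecord,
    scheme: ScoringScheme,
    params: AtramParams,
    min_score: int = 1,
) -> list[Alignment]:
    """Local alignments of target (query) vs the contig, all strands/frames."""
    seed = params.search.seed_for(scheme.mode)
    if scheme.mode == "protein":
        subjects = translate_six_frames(contig.sequence)
    else:
        subjects = [contig.sequence, reverse_complement(contig.sequence)]
    alns: list[Alignment] = []
    for subject in subjects:
        if len(subject) >= seed:
            alns.extend(
                local_alignments(target.sequence, subject, scheme, seed,
                                 min_score=min_score, band=params.search.band)
            )
    return alns


def score_contigs_vs_target(
    contigs: Sequence[Contig],
    target: SequenceRecord,
    scheme: ScoringScheme,
    params: AtramParams,
) -> list[tuple[Contig, int]]:
    """Score each contig against the original target; keep the best few.

    DNA targets are aligned against the contig and its reverse complement;
    protein targets against the contig's six translated frames (best frame
    counts). Contigs below ``contig_min_score`` are dropped; survivors are
    sorted by score (ties by contig_id) and truncated to ``keep_top_contigs``.
    """
    scored = []
    for contig in contigs:
        alns = _contig_alignments(contig, target, scheme, params)
        if not alns:
            continue
        best = max(a.score for a in alns)
        if best >= params.contig_min_score:
            scored.append((contig, best))
    scored.sort(key=lambda cs: (-cs[1], cs[0].contig_id))
    return scored[: params.keep_top_contigs]


def check_autocomplete(
    contig: Contig,
    target: SequenceRecord,
    scheme: ScoringScheme,
    params: AtramParams,
) -> bool:
    """Does this contig reach both the beginning and the end of the query?

    True iff the union of the contig's local alignments to the target touches
    the first and the last ``end_window_fraction`` of the query. The union
    (rather than one spanning alignment) tolerates multi-exon targets whose
    alignment to a genomic contig breaks at introns.
    """
    L = len(target.sequence)
    w = max(1, math.ceil(params.end_window_fraction * L))
    alns = _contig_alignments(contig, target, scheme, params,
                              min_score=params.search.min_score_for(scheme.mode))
    if not alns:
        return False
    lo = min(a.query_span[0] for a in alns)
    hi = max(a.query_span[1] for a in alns)
    return lo < w and hi > L - w


def converged(current: Sequence[Contig], previous: Sequence[Contig]) -> bool:
    """Multisets of canonical-orientation sequences equal (ids/order ignored)."""
    return Counter(c.canonical() for c in current) == Counter(
        c.canonical() for c in previous
    )


def run_atram(
    db: ShardedDatabase,
    target: SequenceRecord,
    params: AtramParams | None = None,
    mode: Literal["auto", "dna", "protein"] = "auto",
) -> AtramResult:
    """Run the full iterative search-and-assemble loop for one target."""
    if params is None:
        params = AtramParams()
    if db.total_pairs == 0:
        raise ValueError("empty read database")
    target_scheme = _target_scheme(target, mode)
    if mode == "dna" and looks_like_protein(target.sequence):
        raise ValueError(f"target {target.id!r} contains amino-acid residues")
    dna_scheme = ScoringScheme.dna()
    search_params = (
        params.search
        if params.search.fraction == params.fraction
        else SearchParams(**{**params.search.__dict__, "fraction": params.fraction})
    )

    trace: list[IterationRecord] = []
    prev_kept: list[Contig] = []
    prev_scores: list[int] = []

    for iteration in range(params.max_iterations):
        if iteration == 0:
            queries = [target]
            scheme = target_scheme
        else:
            queries = [
                SequenceRecord(id=c.contig_id, sequence=c.sequence)
                for c in prev_kept
            ]
            scheme = dna_scheme
        stats: dict = {}
        pool = gather_read_pool(db, queries, scheme, search_params, stats=stats)
        rec = IterationRecord(
            iteration=iteration, n_hits=stats.get("n_hits", 0),
            n_pairs_in_pool=len(pool), contigs=[], kept_contigs=[],
            kept_scores=[], status="continue",
        )
        if not pool:
            rec.status = "no_hits"
            trace.append(rec)
            break
        reads = [r for p in pool for r in (p.read1, p.read2)]
        contigs = assemble_reads(reads, params.assembly, params.assembler_backend)
        rec.contigs = contigs
        scored = score_contigs_vs_target(contigs, target, target_scheme, params)
        rec.kept_contigs = [c for c, _ in scored]
        rec.kept_scores = [s for _, s in scored]
        if not scored:
            rec.status = "no_hits"
            trace.append(rec)
            break
        if params.autocomplete and any(
            check_autocomplete(c, target, target_scheme, params)
            for c, _ in scored
        ):
            rec.status = "autocomplete"
            trace.append(rec)
            break
        if iteration > 0 and converged(rec.kept_contigs, prev_kept):
            rec.status = "converged"
            trace.append(rec)
            break
        if iteration == params.max_iterations - 1:
            rec.status = "max_iterations"
            trace.append(rec)
            break
        trace.append(rec)
        prev_kept = rec.kept_contigs
        prev_scores = rec.kept_scores

    last = trace[-1]
    if last.kept_contigs:
        final, scores = last.kept_contigs, last.kept_scores
    else:
        # a no_hits round after a productive one: the earlier partial
        # assembly is still the result
        final, scores = prev_kept, prev_scores
    best = final[scores.index(max(scores))] if final else None
    return AtramResult(
        target_id=target.id,
        final_contigs=final,
        best_contig=best,
        trace=trace,
        termination=last.status,
    )
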