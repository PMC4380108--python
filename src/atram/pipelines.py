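"""Multi-sample x multi-target pipelines.

``assembly_pipeline`` runs the iterative assembler over a grid of read
databases and target loci, producing putative orthologs per (sample, target)
cell; one failing cell never aborts the grid. ``alignment_pipeline`` then
keeps, per target, each sample's best contig that passes the reciprocal
best-hit orthology test and stacks the survivors into one multiple alignment
per target, anchored on the reference target's coordinates (insertions
relative to the reference are gap-padded across samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assembler import Contig
from .iterate import AtramParams, run_atram
from .postprocess import best_metric_alignment, reciprocal_best_hit
from .search import ScoringScheme
from .seq_io import SequenceRecord, write_fasta
from .shard_db import ShardedDatabase, load_database

__all__ = [
    "PipelineManifest",
    "read_manifest",
    "assembly_pipeline",
    "alignment_pipeline",
    "stack_on_reference",
]

log = logging.getLogger("atram.pipelines")

RESULT_COLUMNS = [
    "sample_id", "target_id", "status", "iterations",
    "best_contig_length", "best_score", "n_contigs",
]


@dataclass
class PipelineManifest:
    samples: list[tuple[str, Path]]
    targets: list[SequenceRecord]
    params: AtramParams = field(default_factory=AtramParams)
    output_dir: Path = Path("atram_out")
    mode: str = "auto"

    def validate(self) -> list[str]:
        errors = []
        sample_ids = [s for s, _ in self.samples]
        if not self.samples:
            errors.append("no samples listed")
        if len(set(sample_ids)) != len(sample_ids):
            errors.append("sample ids are not unique")
        if not self.targets:
            errors.append("no targets listed")
        target_ids = [t.id for t in self.targets]
        if len(set(target_ids)) != len(target_ids):
            errors.append("target ids are not unique")
        for sid, path in self.samples:
            if not (Path(path) / "manifest.txt").exists():
                errors.append(f"sample {sid!r}: no database at {path}")
        return errors


def read_manifest(path: str | Path, params: AtramParams | None = None) -> PipelineManifest:
    """Parse a plain-text manifest.

    ``key=value`` lines for scalars (``output_dir``, ``mode``), plus table
    lines ``sample <id> <db_dir>`` and ``target <fasta_path>`` (every record
    in a target FASTA becomes one target).
    """
    from .seq_io import read_sequences

    base = Path(path).parent
    samples: list[tuple[str, Path]] = []
    targets: list[SequenceRecord] = []
    scalars: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("sample "):
                _, sid, db = line.split(None, 2)
                samples.append((sid, base / db))
            elif line.startswith("target "):
                _, fasta = line.split(None, 1)
                targets.extend(read_sequences(base / fasta))
            elif "=" in line:
                key, _, value = line.partition("=")
                scalars[key.strip()] = value.strip()
    return PipelineManifest(
        samples=samples,
        targets=targets,
        params=params or AtramParams(),
        output_dir=base / scalars.get("output_dir", "atram_out"),
        mode=scalars.get("mode", "auto"),
    )


def assembly_pipeline(
    manifest: PipelineManifest, write_outputs: bool = True
) -> pd.DataFrame:
    """Run every (sample, target) cell; one row per cell, failures recorded."""
    errors = manifest.validate()
    if errors:
        raise ValueError("manifest validation failed: " + "; ".join(errors))
    out = Path(manifest.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    rows = []
    dbs: dict[str, ShardedDatabase] = {}
    for sid, db_path in manifest.samples:
        dbs[sid] = load_database(db_path)
    for sid, _ in manifest.samples:
        for target in manifest.targets:
            try:
                result = run_atram(dbs[sid], target, manifest.params, mode=manifest.mode)
                best = result.best_contig
                best_score = (
                    max(result.trace[-1].kept_scores)
                    if result.trace[-1].kept_scores
                    else (max(result.trace[-2].kept_scores)
                          if len(result.trace) > 1 and result.trace[-2].kept_scores
                          else 0)
                )
                rows.append({
                    "sample_id": sid, "target_id": target.id,
                    "status": result.termination,
                    "iterations": len(result.trace),
                    "best_contig_length": best.length if best else 0,
                    "best_score": best_score,
                    "n_contigs": len(result.final_contigs),
                })
                log.info("cell %s x %s: %s (%d contigs)",
                         sid, target.id, result.termination, len(result.final_contigs))
                if write_outputs:
                    stem = out / f"{sid}__{target.id}"
                    recs = [
                        SequenceRecord(id=f"{sid}.{c.contig_id}", sequence=c.sequence)
                        for c in result.final_contigs
                    ]
                    write_fasta(recs, f"{stem}.all.fasta")
                    write_fasta(recs[:1] if best is None else [
                        SequenceRecord(id=f"{sid}.{best.contig_id}", sequence=best.sequence)
                    ], f"{stem}.best.fasta")
                    with open(f"{stem}.trace.tsv", "wt") as fh:
                        fh.write("iteration\tn_hits\tn_pairs\tn_contigs\tstatus\n")
                        for r in result.trace:
                            fh.write(f"{r.iteration}\t{r.n_hits}\t{r.n_pairs_in_pool}"
                                     f"\t{len(r.contigs)}\t{r.status}\n")
            except Exception as exc:  # per-cell isolation: record, keep going
                log.warning("cell %s x %s failed: %s", sid, target.id, exc)
                rows.append({
                    "sample_id": sid, "target_id": target.id, "status": "error",
                    "iterations": 0, "best_contig_length": 0,
                    "best_score": 0, "n_contigs": 0,
                })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if write_outputs:
        df.to_csv(out / "results.tsv", sep="\t", index=False)
    return df


def stack_on_reference(
    reference: SequenceRecord,
    contigs: dict[str, Contig | SequenceRecord],
    scheme: ScoringScheme | None = None,
) -> list[SequenceRecord]:
    """Reference-anchored stacking of per-sample contigs into one alignment.

    Each contig is pairwise-aligned to the reference (best orientation);
    columns are merged on reference coordinates, with insertions relative to
    the reference padded with gaps in every other row. The reference itself
    is the first row.
    """
    scheme = scheme or ScoringScheme.dna()
    ref_len = len(reference.sequence)
    per_sample_cells: dict[str, list[str]] = {}
    per_sample_ins: dict[str, dict[int, str]] = {}
    for sid, contig in sorted(contigs.items()):
        pair = best_metric_alignment(contig, reference, scheme)
        cols = list(zip(pair.seq_a, pair.seq_b))
        # contig overhangs beyond the reference are not part of the locus
        ref_cols = [i for i, (_, cb) in enumerate(cols) if cb != "-"]
        cols = cols[ref_cols[0] : ref_cols[-1] + 1] if ref_cols else []
        cells = ["-"] * ref_len
        ins: dict[int, str] = {}
        r = 0
        for ca, cb in cols:
            if cb == "-":
                if ca != "-":
                    ins[r] = ins.get(r, "") + ca
            else:
                if ca != "-":
                    cells[r] = ca
                r += 1
        per_sample_cells[sid] = cells
        per_sample_ins[sid] = ins
    ins_len = {
        r: max(len(per_sample_ins[s].get(r, "")) for s in per_sample_ins)
        for r in range(ref_len + 1)
    } if per_sample_ins else {}

    def build_row(cells: list[str] | None, ins: dict[int, str]) -> str:
        parts = []
        for r in range(ref_len + 1):
            gap_block = ins_len.get(r, 0)
            if gap_block:
                block = ins.get(r, "")
                parts.append(block + "-" * (gap_block - len(block)))
            if r < ref_len:
                parts.append(reference.sequence[r] if cells is None else cells[r])
        return "".join(parts)

    rows = [SequenceRecord(id=reference.id, sequence=build_row(None, {}))]
    for sid in sorted(per_sample_cells):
        rows.append(
            SequenceRecord(id=sid, sequence=build_row(per_sample_cells[sid],
                                                      per_sample_ins[sid]))
        )
    return rows


def alignment_pipeline(
    manifest: PipelineManifest,
    reference_targets: Sequence[SequenceRecord] | None = None,
    proteome: Sequence[SequenceRecord] | None = None,
    write_outputs: bool = True,
) -> dict[str, list[SequenceRecord]]:
    """Per-target multiple alignments of orthology-passing best contigs.

    Contigs are filtered by the reciprocal best-hit test against ``proteome``
    (default: the translated reference targets) before alignment; a target
    with fewer than two passing samples is skipped with a log entry.
    """
    from Bio.Seq import Seq

    errors = manifest.validate()
    if errors:
        raise ValueError("manifest validation failed: " + "; ".join(errors))
    reference_targets = list(reference_targets or manifest.targets)
    ref_by_id = {t.id: t for t in reference_targets}
    if proteome is None:
        proteome = []
        for t in reference_targets:
            from .iterate import looks_like_protein

            seq = t.sequence if looks_like_protein(t.sequence) else str(
                Seq(t.sequence).translate()
            ).rstrip("*")
            proteome.append(SequenceRecord(id=t.id, sequence=seq))

    out = Path(manifest.output_dir)
    dbs = {sid: load_database(p) for sid, p in manifest.samples}
    alignments: dict[str, list[SequenceRecord]] = {}
    for target in manifest.targets:
        ref = ref_by_id[target.id]
        passing: dict[str, Contig] = {}
        for sid, _ in manifest.samples:
            result = run_atram(dbs[sid], target, manifest.params, mode=manifest.mode)
            if result.best_contig is None:
                continue
            call = reciprocal_best_hit(result.best_contig, target.id, list(proteome))
            if call.is_ortholog:
                passing[sid] = result.best_contig
            else:
                log.info("target %s sample %s: best contig fails orthology (%s)",
                         target.id, sid, call.best_reference_hit)
        if len(passing) < 2:
            log.info("target %s: %d passing sample(s), alignment skipped",
                     target.id, len(passing))
            continue
        ref_dna = ref_by_id[target.id]
        rows = stack_on_reference(ref_dna, passing)
        alignments[target.id] = rows
        if write_outputs:
            out.mkdir(parents=True, exist_ok=True)
            write_fasta(rows, out / f"{target.id}.aligned.fasta")
    return alignments
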