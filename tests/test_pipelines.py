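import numpy as np
import pytest
from click.testing import CliRunner

from atram.iterate import AtramParams
from atram.pipelines import (
    PipelineManifest,
    alignment_pipeline,
    assembly_pipeline,
    read_manifest,
    stack_on_reference,
)
from atram.postprocess import make_aligned_pair, p_distance
from atram.readsim import ReadSimParams, mutate_homolog, simulate_paired_reads
from atram.seq_io import SequenceRecord, write_fasta
from atram.shard_db import build_database

from conftest import random_dna


@pytest.fixture(scope="module")
def grid(tmp_path_factory):
    """Two samples (reference genome + a 5% diverged homolog) x 3 targets."""
    from atram.readsim import simulate_genome

    base = tmp_path_factory.mktemp("grid")
    genome = simulate_genome(30_000, 3, seed=61)
    samples = []
    for sid, g, seed in [
        ("ref", genome, 62),
        ("div5", mutate_homolog(genome, 0.05, seed=63), 64),
    ]:
        pairs = simulate_paired_reads(
            g, ReadSimParams(coverage=30, substitution_error_rate=0.0, seed=seed)
        )
        db_dir = base / f"db_{sid}"
        build_database(pairs, n_shards=2, out_dir=db_dir)
        samples.append((sid, db_dir))
    targets = [genome.coding_sequence(x.gene_id) for x in genome.genes]
    return base, genome, samples, targets


def test_assembly_pipeline_grid_completeness(grid):
    base, genome, samples, targets = grid
    manifest = PipelineManifest(
        samples=samples, targets=targets,
        params=AtramParams(autocomplete=True),
        output_dir=base / "out",
    )
    df = assembly_pipeline(manifest)
    assert len(df) == len(samples) * len(targets)
    assert set(df["status"]) <= {"autocomplete", "converged", "max_iterations"}
    assert (df["best_contig_length"] > 0).all()
    assert (base / "out" / "results.tsv").exists()
    assert (base / "out" / "ref__gene001.best.fasta").exists()
    assert (base / "out" / "ref__gene001.trace.tsv").exists()


def test_assembly_pipeline_absent_target_isolated(grid, rng):
    base, genome, samples, targets = grid
    absent = SequenceRecord(id="absent", sequence=random_dna(rng, 500))
    manifest = PipelineManifest(
        samples=samples[:1], targets=[targets[0], absent],
        params=AtramParams(autocomplete=True),
        output_dir=base / "out2",
    )
    df = assembly_pipeline(manifest)
    assert len(df) == 2
    by_target = df.set_index("target_id")
    assert by_target.loc["absent", "status"] == "no_hits"
    assert by_target.loc[targets[0].id, "status"] != "no_hits"


def test_assembly_pipeline_validates_manifest(grid):
    base, _, samples, _ = grid
    manifest = PipelineManifest(samples=samples, targets=[],
                                output_dir=base / "out3")
    with pytest.raises(ValueError, match="no targets"):
        assembly_pipeline(manifest)


def test_stack_on_reference_identical_rows(rng):
    ref = SequenceRecord(id="ref", sequence=random_dna(rng, 300))
    from atram.assembler import Contig

    contigs = {
        s: Contig(contig_id=s, sequence=ref.sequence, mean_kmer_coverage=1)
        for s in ("s1", "s2", "s3")
    }
    rows = stack_on_reference(ref, contigs)
    assert len(rows) == 4  # reference + 3 samples
    assert len({len(r.sequence) for r in rows}) == 1
    assert all(r.sequence == ref.sequence for r in rows)  # no gap columns


def test_alignment_pipeline_pairwise_distances_track_divergence(grid):
    base, genome, samples, targets = grid
    manifest = PipelineManifest(
        samples=samples, targets=targets,
        params=AtramParams(autocomplete=True),
        output_dir=base / "aln",
    )
    alignments = alignment_pipeline(manifest)
    assert alignments  # at least one target aligned
    for tid, rows in alignments.items():
        by_id = {r.id: r for r in rows}
        assert set(by_id) == {tid, "ref", "div5"}
        pair = make_aligned_pair(by_id["ref"].sequence, by_id["div5"].sequence)
        d = p_distance(pair)
        n = pair.comparable_sites
        assert abs(d - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n) + 0.01


def test_read_manifest_parsing(tmp_path, grid):
    _, genome, samples, targets = grid
    write_fasta(targets, tmp_path / "targets.fasta")
    text = "output_dir=results\nmode=auto\n"
    for sid, db in samples:
        text += f"sample {sid} {db}\n"
    text += "target targets.fasta\n"
    (tmp_path / "manifest.txt").write_text(text)
    manifest = read_manifest(tmp_path / "manifest.txt")
    assert [s for s, _ in manifest.samples] == ["ref", "div5"]
    assert len(manifest.targets) == 3
    assert manifest.output_dir == tmp_path / "results"
    assert manifest.validate() == []


def test_cli_format_db_and_atram_roundtrip(tmp_path, grid):
    from atram.cli import atram_cmd, format_db_cmd
    from atram.seq_io import write_fastq

    _, genome, _, targets = grid
    pairs = simulate_paired_reads(
        genome, ReadSimParams(coverage=25, substitution_error_rate=0.0, seed=65)
    )
    write_fastq(pairs, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
    runner = CliRunner()
    res = runner.invoke(format_db_cmd, [
        "--reads", str(tmp_path / "r1.fastq"),
        "--reads2", str(tmp_path / "r2.fastq"),
        "--out", str(tmp_path / "db"), "--shards", "2",
    ])
    assert res.exit_code == 0, res.output
    assert "pairs in 2 shard(s)" in res.output

    write_fasta([targets[0]], tmp_path / "t.fasta")
    res = runner.invoke(atram_cmd, [
        "--db", str(tmp_path / "db"),
        "--target", str(tmp_path / "t.fasta"),
        "--out", str(tmp_path / "out"),
        "--autocomplete",
    ])
    assert res.exit_code == 0, res.output
    best = (tmp_path / "out" / f"{targets[0].id}.best.fasta").read_text()
    assert best.startswith(">")
    trace = (tmp_path / "out" / f"{targets[0].id}.trace.tsv").read_text()
    assert trace.splitlines()[0].startswith("iteration")


def test_cli_stats(tmp_path, grid):
    from atram.cli import stats_cmd

    _, genome, _, targets = grid
    gene = genome.genes[0]
    span = gene.span
    locus = genome.sequence[span[0] - 200 : span[1] + 200]
    write_fasta([SequenceRecord(id=targets[0].id, sequence=locus)],
                tmp_path / "contigs.fasta")
    write_fasta(targets, tmp_path / "refs.fasta")
    proteome = [genome.protein(x.gene_id) for x in genome.genes]
    write_fasta(proteome, tmp_path / "prot.fasta")
    runner = CliRunner()
    res = runner.invoke(stats_cmd, [
        "--contigs", str(tmp_path / "contigs.fasta"),
        "--reference", str(tmp_path / "refs.fasta"),
        "--proteome", str(tmp_path / "prot.fasta"),
        "--out", str(tmp_path / "stats.tsv"),
    ])
    assert res.exit_code == 0, res.output
    lines = (tmp_path / "stats.tsv").read_text().splitlines()
    header = lines[0].split("\t")
    row = dict(zip(header, lines[1].split("\t")))
    assert float(row["percent_coverage"]) == 1.0
    assert float(row["p_distance"]) == 0.0
    assert row["is_ortholog"] == "true"
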