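# atram — targeted iterative assembly of loci from paired-end short reads

Phylogenomic projects rarely need whole-genome assemblies: they need a few
hundred to a few thousand homologous loci from each of many taxa, often with
no close reference genome. `atram` assembles exactly those loci, one at a
time, directly from a single paired-end short-read library — including
libraries from species tens of millions of years divergent from the taxon
that supplied the query sequences.

## The method

The library is first **sharded**: fragments (read pairs) are distributed
into approximately equal partitions by a salted hash of the fragment id.
Because read names are unrelated to genomic content, every shard is a random
sample of the run; each shard indexes its end-1 reads for search and keeps a
mate store so the partner of any hit is retrievable in O(1). Searching a
fraction *f* of the shards downsamples effective coverage by *f* without
bias, which matters when a target (e.g. rDNA, organellar DNA) is covered far
above the 20–50× that assembly wants.

Assembly of one locus is then an iterative search-and-assemble loop:

1. **Iteration 0** — the user's query (DNA, or protein for divergent taxa)
   is searched against each shard with a seed-and-extend local aligner:
   exact words (28 nt for DNA, mirroring megablast's word size; 4 aa for
   translated search against all six reading frames of each read) are
   extended in both directions with a banded, affine-gap X-drop dynamic
   program. Top hits per shard and their mates form the read pool.
2. The pool is assembled with a built-in de Bruijn graph assembler
   (canonical 31-mers, unitig extraction, abundance and weak-branch
   filtering), or a plugin assembler.
3. Contigs are scored against the *original* target; the best few become the
   queries of the next iteration. From iteration 1 on the queries are
   nucleotide contigs from the library itself, so matching reads are
   identical rather than merely similar, and the contig grows outward by
   roughly an insert length per iteration.
4. The loop stops on **autocomplete** (a contig's alignments reach both the
   beginning and end of the query), **convergence** (the contig set repeats
   exactly), **no_hits**, or the iteration cap.

The key asymmetry the tool exploits: at 20% nucleotide divergence the
probability that a 28-base DNA word survives unchanged is 0.8²⁸ ≈ 0.002 —
DNA queries find essentially nothing — while 4-residue amino-acid words
survive easily, so protein queries still seed the locus. Once iteration 0
lands anywhere on the locus, all later iterations run in identical-sequence
space and divergence no longer matters.

Validation follows standard practice: **percent coverage** of the reference
by the contig (overlap alignment, both orientations, intron-tolerant gap
costs), **uncorrected p-distance** (proportion of differing sites among
aligned non-gap sites, no substitution-model correction), and a **reciprocal
best-hit orthology test** (the contig's six translated frames are searched
against the entire reference protein set; the assembly is orthologous iff
its own query gene is the top hit).

A bundled simulator (`atram.readsim`) generates genomes with intron-bearing
genes, diverged homologs (i.i.d. substitutions), and paired-end libraries
with realistic insert sizes and error rates, so the whole pipeline is
testable without downloading anything.

## Worked example

```python
from atram import (
    AtramParams, ReadSimParams, build_database, run_atram,
    simulate_genome, simulate_paired_reads, percent_coverage, p_distance,
)
from atram.postprocess import best_metric_alignment

genome = simulate_genome(length=50_000, n_genes=4, seed=7)
pairs = simulate_paired_reads(genome, ReadSimParams(coverage=30, seed=8))
db = build_database(pairs, n_shards=2)

target = genome.coding_sequence("gene002")      # spliced coding DNA
result = run_atram(db, target, AtramParams(autocomplete=True))

best = result.best_contig
print(f"termination : {result.termination} after {len(result.trace)} iteration(s)")
print(f"best contig : {best.contig_id}, {best.length} bp, "
      f"mean k-mer coverage {best.mean_kmer_coverage:.1f}")
print(f"coverage    : {percent_coverage(best, target):.3f}")
print(f"p-distance  : {p_distance(best_metric_alignment(best, target)):.4f}")
```

prints

```
termination : autocomplete after 1 iteration(s)
best contig : c1, 1010 bp, mean k-mer coverage 14.9
coverage    : 1.000
p-distance  : 0.0000
```

The 1010-bp contig is the full genomic locus — both exons, the intron, and
flanking sequence — recovered from a 564-bp spliced query: coverage 1.000
means every query base is covered, and p-distance 0 means the assembled
exons are identical to the truth. `result.trace` records per-iteration hit
counts, pool sizes and contig counts.

The same loop from the shell:

```sh
format_db --reads R1.fastq.gz --reads2 R2.fastq.gz --out lib_db --shards 4
atram --db lib_db --target genes.fasta --out out/ --autocomplete
atram-stats --contigs out/gene001.best.fasta --reference genes.fasta \
            --proteome proteins.fasta --out stats.tsv
```

plus `assembly-pipeline` / `alignment-pipeline` for sample × gene grids
(see `atram.pipelines`), and `atram-sim` for the simulator.

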