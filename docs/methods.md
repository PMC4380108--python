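# Methods

This note documents the models, algorithms and numerical choices behind the
package, what the simulator does and does not emulate, and the design
decisions that were genuinely open.

## Sharded read database

Pairs are assigned to shards by a salted MD5 of the *pair* id (never a read
id, so mates always co-locate). MD5 rather than the language's built-in
string hash because the latter is randomized per process and the layout must
be reproducible; the salt is recorded in the manifest. For hash-random ids
the shard sizes are Binomial(n, 1/N), so with ≥1000 pairs the max/mean size
ratio stays well under 1.5. The on-disk format is deliberately plain text —
a `key=value` manifest plus one `pair_id, read1, read2` TSV per shard — and
rebuilding from the same pairs and salt is byte-identical.

Only end-1 reads are searchable; mates are reached exclusively through the
mate store. Rather than freezing one k-mer size into the on-disk index, each
shard builds its postings index lazily at the word size a search actually
requests (nucleotide k-mers are stored canonically, making both read
orientations searchable without duplicating reads; the translated-frame
index for protein search is built the same way). The manifest's `index_kmer`
records the default. Indexes are cached per shard, so a multi-gene run pays
the build once.

The default shard count is `ceil(library_bytes / 250 MB)` with a floor of 1;
the bundled experiments use 4 shards, because the per-shard top-N hit cap
(default 100) times the shard count bounds the read pool a locus can recruit
per iteration, and a 3–5 kb locus at 30–40× needs several hundred pairs.

## Search: seed-and-extend with X-drop

The internal search engine replaces an external BLAST call so the pipeline
is self-contained and deterministic. Exact shared words seed a gapped
extension in both directions, computed by a banded affine dynamic program
(band ±16 diagonals) that prunes any cell falling more than X = 30 below the
running best. Scores are raw alignment scores — they are deterministic and
independent of database size, unlike E-values. Ties in hit ranking break
lexicographically by pair id so top-N truncation is reproducible.

Default word sizes: 28 nt for DNA and 4 aa for protein queries. The DNA
value mirrors megablast's default word size and is what produces the
method's characteristic behaviour on divergent material: at 20% nucleotide
divergence, P(exact 28-mer) = 0.8²⁸ ≈ 0.002, so DNA queries find almost no
seeds, while protein search (BLOSUM62 over all six reading frames of each
read, stops scored as universal mismatches) still seeds readily — amino-acid
4-mers survive ~37% aa divergence at usable rates. A word size near 12 would
erase this contrast entirely: 0.8¹² ≈ 0.07 gives several expected seeds per
100-bp read even at 20% divergence.

The scoring defaults (+5/−4, gap open −8, extend −2) sit in the "linear
phase" for random DNA: unanchored local alignment scores of random pairs
grow linearly with length, and an unanchored or unlimited extension will
happily wander through random sequence collecting mosaic matches. The
X-drop rule is what keeps extensions honest under these costs; X = 30 was
calibrated so that a seeded extension recovers the full Smith–Waterman
optimum in >95% of random trials (at X = 20 the recovery rate is ~89%,
because optimal alignments occasionally cross score valleys deeper than 20).

`min_score` defaults: 40 (DNA), 35 (protein). These gate what counts as a
hit; because candidates must share an exact seed anyway, the thresholds
mainly suppress marginal read-edge overlaps.

## Assembly: de Bruijn unitigs with minimal cleaning

Nodes are canonical 31-mers (lexicographic min of word and reverse
complement; k is required odd so no word is its own reverse complement)
counted over both mates and strands; contigs are maximal non-branching
paths, emitted in canonical orientation and ranked deterministically by
length then sequence. Two cleaning steps only:

* `min_kmer_count = 2` removes sequencing-error singletons (set it to 1 for
  error-free fixtures, where end k-mers may be seen once);
* **weak-branch trimming**: at any branch, children whose k-mer count is at
  most 0.2× their strongest sibling are removed. At 40× depth with a 0.5%
  substitution error rate, two reads sharing an error at the same site (same
  substituted base) occur about 0.0065 times per position — roughly 20
  surviving count-2 bubble paths per 3-kb locus — and without this filter
  each one splits the contig. A genuine repeat branch has balanced coverage
  on both children and still splits the path; on error-free input there are
  no branches and the filter is a no-op, so the exact-reconstruction
  properties are untouched.

There is no bubble popping beyond this, no tip clipping and no scaffolding:
the pools are small and locus-restricted, and heavier machinery belongs to
plugin assemblers (which must only honor the `assemble_reads` signature and
be deterministic given their seed).

## The iteration loop

Iteration 0 searches with the user's query in its own alphabet; protein
targets force translated search. All later iterations search with the kept
contigs in DNA mode — the queries are now nucleotide sequences drawn from
the library itself. After each assembly, contigs are scored against the
*original* target only (protein targets against the contig's best
translated frame); filtering against intermediate contigs would let the
assembly drift off-locus. Survivors (score ≥ 70, top 5) seed the next round.

Stopping rules, in order of precedence within an iteration: no pool or no
kept contigs (`no_hits`; if an earlier iteration succeeded, its contigs are
returned — a partial assembly is a result); `autocomplete`; `converged`
(kept-contig multiset identical to the previous iteration, comparing
canonical sequences only — ids and order are meaningless); iteration cap
(default 5, counting iteration 0 as the first).

Autocomplete asks whether the union of a contig's local alignments to the
target touches both the first and last 5% of the target
(`end_window_fraction = 0.05`). The union — rather than one spanning
alignment — is deliberate: a genomic contig aligns to a spliced or protein
target in exon-sized pieces, and requiring a single alignment to span both
ends would never fire for multi-exon genes. The 5% window tolerates tiny
terminal exons that cannot anchor an alignment on their own, the known
failure mode of end-anchored completion checks.

## Validation metrics

`semi_global_align` is an overlap alignment (free end gaps on both
sequences) with full traceback and fixed tie-breaking (aligned column >
gap-in-first > gap-in-second). For the coverage and p-distance metrics the
two gap directions carry different costs: unaligned contig bases (introns,
when a genomic contig is aligned to a spliced reference) cost open −12,
extend −1, while unaligned reference bases pay the scheme's normal costs.
With symmetric costs the intron gap is so expensive that a mosaic
mis-alignment of the target into flanking sequence can outscore the true
exon alignment, corrupting both metrics; making expected insertions cheap
removes that failure while leaving substitutions properly penalized.

Percent coverage counts reference positions aligned to contig symbols
(reference positions, not alignment columns), best orientation wins, ties
prefer forward. p-distance is differing/comparable sites, where comparable
excludes gaps, N and ambiguity codes on either side; an alignment with no
comparable sites reports a missing value rather than 0. The reciprocal
best-hit test searches the contig's translated frames against every
reference protein with the same seeded search engine; score ties break by
protein id ascending, so a tie with the true gene can fail the test —
conservative by construction.

## Simulator

`simulate_genome` draws a uniform random background and places
non-overlapping genes (2–4 exons of 50–100 codons built from sense codons
only, so translations carry no internal stops; introns 50–500 bp; ≥500 bp
flanks; either strand). `mutate_homolog` applies i.i.d. substitutions to a
uniformly random different base — no indels, so coordinates and reading
frames are preserved and realized divergence is binomial around the nominal
rate. `simulate_paired_reads` draws fragment lengths from
Normal(300, 30) truncated at the read length, uniform starts, a uniformly
random sequencing strand per fragment (read 1 is the 5′ end of the
sequenced strand — without strand randomization, pools can only recruit
rightward and contigs stall at their left edges), and i.i.d. substitution
errors (default 0.5%). `n_pairs = round(coverage × L / (2 × read_length))`.

What the simulator does **not** emulate: indel divergence and indel
sequencing errors, quality-dependent and GC-biased error profiles, repeat
families and paralogous gene copies, alternative splicing, and coverage
unevenness beyond Poisson sampling. Passing tests therefore demonstrate the
machinery (sharding, translated search, iterative recruitment, assembly,
metrics) under substitution-only divergence; they do not certify behaviour
on repeat-rich or indel-heavy real libraries, where a plugin assembler with
bubble popping may outperform the internal one.

## Study conditions and problem sizes

The end-to-end experiments (`atram.experiments`, also driven by
`scripts/acceptance.py`) use a 100 kb genome with 10 intron-bearing genes:
clean recovery at 30× error-free, noisy recovery at 40× with 0.5% error,
and the divergence contrast at 10% and 20% nucleotide divergence with 30×
libraries (protein and DNA queries both taken from the *original* genome).
The orthology sweep uses a 50-gene, 250 kb proteome. These sizes keep a full
study around a minute on one CPU while leaving each locus at realistic
coverage; recovery rates are computed over 10 genes, so single-gene
fluctuations move them by 10 points.

## Known limitations

* The search engine has no E-value statistics; raw score thresholds are not
  comparable across scoring schemes.
* One seed cluster is extended per diagonal band; a read matching the query
  in two widely separated blocks reports only the better block (reads are
  ~100 bp, so this costs little).
* `fraction` selects a prefix of shards rather than a random subset — valid
  because shards are themselves random samples, but it means the same
  fraction always reads the same shards.
* The alignment pipeline's reference-anchored stacking is not a true
  multiple alignment: insertions relative to the reference are left-packed
  per sample, not aligned to each other. For publication-grade alignments
  feed the per-sample FASTAs to a multiple aligner.
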