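# Methods

## Model and assumptions

`readsieve` solves a gene-assignment problem: given a panel *G* of gene
locus sequences and an RNA-Seq sample, return for each read the set of
panel genes that satisfy the shared-base criterion (README). The
approach assumes:

* reads are substrings of transcripts, which are exon concatenations of
  a gene locus — so every k-mer of a read that lies within one exon is
  a k-mer of the locus, while k-mers spanning exon junctions generally
  are not (the union-of-covered-bases count absorbs this loss: the
  bases on both sides of a junction are still covered by intra-exon
  windows, so a junction read loses at most the sub-k overhang of a
  short exon overlap);
* substitutions (sequencing errors or polymorphisms) kill the ≤ k
  windows that span them; the τ threshold tolerates this as long as the
  surviving windows cover ≥ τ·|s| bases;
* the double-stranded origin of reads is handled by canonical k-mers,
  so strandedness never needs to be known.

No alignment, spliced or otherwise, is performed, and collision-induced
candidate genes are never verified: the structure trades a small false
positive rate for speed and memory, and false positives only reduce
precision of the filter, never its recall.

## Data structure

* **Bloom filter BF** (m bits, default 2³³ = 1 GB): one hash function
  only. At panel scale the filter is very sparse (load factor ≈ 10⁻³
  for a 100-gene panel at m = 2³³), so a single hash costs little
  accuracy and halves memory traffic versus multi-hash filters.
  The hash is a Murmur3-style 64-bit finalizer (fmix64) applied to the
  2-bit-packed canonical value XOR a mixed seed, reduced mod m — pure
  integer mixing, identical on every platform; the seed defaults to a
  fixed documented constant and is overridable.
* **Gene-ID vector I and boundary vector P**: construction appends gene
  IDs in gene-scan order, deduplicating per gene, so every delimited
  segment of I is strictly increasing. Rank/select is provided by a
  per-64-bit-word cumulative popcount table (rank is O(1); select
  binary-searches the table and scans one word). The query path caches
  the array of 0-based segment boundaries (positions of the 1s of P) at
  load time, so a lookup is one rank on BF plus two array reads; P
  remains the persisted representation.
* **Conventions**: all internal indices are 0-based; `rank1(i)` counts
  set bits in the half-open prefix `[0, i)` and `select1(j)` returns
  the 0-based position of the j-th set bit (j from 1), so
  `select1(rank1(p) + 1) == p` for every set position p — both are
  property-tested against brute force. Since only indexed k-mers set
  bits, a set bit's ordinal among set bits is `rank1(h) + 1` when
  `BF[h] = 1`.
* **Persistence**: a binary container with magic bytes, version, (k, m,
  seed), the gene-name table and the raw words of BF, P and I;
  round-trips are bit-exact and a k mismatch or truncation is a format
  error.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 17 | k-mer length (≤ 32, one 64-bit word); larger k → more precise, less error-tolerant |
| τ | 0.6 | minimum shared-base fraction of the full read length (denominator is \|s\| even when quality masking removed windows) |
| q | 10 | Phred threshold; windows spanning a base with quality < q are skipped (0 disables) |
| m | 2³³ bits | Bloom filter size; tests and the benchmark use 2²⁶–2²² since panel k-mer counts are small |
| mode | multiple | `single` drops reads with >1 tied candidate gene |
| pairing_policy | union | mates are classified independently; `union` co-retains a pair when either mate is assigned, `separate` treats mates as independent reads |

Reads shorter than k produce no windows and are never assigned. Genes
shorter than k keep their ID (stable name table) but contribute no
k-mers; a warning is logged.

## Synthetic data generator

The generator (`readsieve.simulate`) emulates the benchmark conditions
at desk scale: by default 50 gene loci built from i.i.d. random DNA with
2–5 exons (150–600 bp) separated by introns (50–200 bp) — loci of
roughly 2 kb — a 10-gene panel, and 50 000 single-end 100 bp reads.
Reads are drawn from one transcript per gene (all exons concatenated)
with log-normal transcript abundances (σ = 1), uniform start positions,
uniform strand, i.i.d. substitution errors at 0.2% per base, and
Phred-style qualities N(36, 3) clipped to [2, 40] with a 1% per-base
chance of a low-quality dip (Phred 2–9). A segment can optionally be
planted into the first exon of two loci to emulate paralogy and force
tied assignments. The true origin gene (exactly one per read) and the
number of exon junctions each read spans are recorded separately from
the FASTQ.

All randomness is drawn upfront from one seeded generator, so outputs
are byte-reproducible and the stream consumed does not depend on
outcomes (the same seed with error rate 0 yields the same fragments —
used as an oracle in the error-rate test).

What the generator does **not** emulate: indels, coverage biases from
fragmentation/amplification, alternative isoforms, error/quality
correlation (error positions are independent of the simulated quality
dips), and real genomic repeat structure beyond the optional planted
segment. Passing tests therefore demonstrate the correctness of the
index and of the shared-base accounting, and recall under substitution
noise and splicing — not precision on real paralog-rich panels, which
depends on sequence similarity the generator only caricatures.

## Evaluation accounting

Per read, with its single true origin known: an assignment to the
origin (when the origin is in the panel) is one true positive; every
assignment to a non-origin panel gene is one false positive — covering
both misassigned panel-origin reads and captured out-of-panel reads; a
panel-origin read not assigned to its origin is one false negative (at
most one per read). precision = tp/(tp+fp) (reported as null when
undefined), recall = tp/(tp+fn); recall's denominator is exactly the
number of panel-origin reads.

## Numerical and design choices

* Lexicographic canonical comparison is done on the 2-bit encodings
  (A<C<G<T), equivalent to string comparison and branch-free.
* Lowercase input is accepted (soft-masked references); any non-ACGT
  character, IUPAC codes included, invalidates the windows spanning it.
* Accumulators are sparse per-read dictionaries keyed by gene ID; hits
  are typically confined to a handful of genes, so dense |G|-length
  arrays would waste the reset cost.
* Ties are never broken: all maximal-count genes meeting τ are
  reported (multiple) or the read is dropped (single).
* Classification is fully deterministic: the only seeds in the package
  belong to the simulator and the index hash. Multi-worker runs split
  reads into batches, process them in forked workers and concatenate in
  submission order; the assignment table is additionally sorted by
  (read_id, gene_name) before writing.
* Degenerate inputs: empty panels, duplicate gene names, k > 32, m < 1
  and τ ∉ (0, 1] are rejected; an empty sample yields an empty
  assignment; malformed FASTQ records are skipped with a warning
  (or abort under `--strict`).

## Benchmark scale

The recall benchmark (`scripts/acceptance.py`, also a test) runs the
full pipeline on the generator's default conditions — 50 loci, 10-gene
panel, 50 000 reads, m = 2²⁶ — which completes in well under a minute
on one CPU while leaving the per-read statistics (≈ 9 000 panel-origin
reads) large enough for a stable recall estimate. The index/oracle
equivalence suite uses 100 random panels of 2–12 genes (200–900 bp) at
m = 2²², where the exact dictionary is cheap to enumerate.

## Known limitations

* Counts for collision-induced spurious genes are not capped or
  verified; with realistic m they are far below τ·|s| in practice.
* Paired-end mates are classified independently; there is no
  fragment-level model linking them beyond the retention policy.
* The index must fit in memory; there is no on-disk query mode.
* Precision measured on the synthetic data (≈ 100% with a random-DNA
  panel) overstates real-data precision, where similar genes share
  k-mers; recall is the metric the generator is designed to probe.
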