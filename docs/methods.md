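# Methods

## Model

Each sample (a file of sequences, or a single record) is represented by the
set of its length-`k` windows. A Bloom filter of `m` bits with `h` hash
functions stores the set: inserting a k-mer sets the bits at its `h` hash
positions; membership holds when all `h` bits are set. False negatives are
impossible; false positives occur at approximately

    fpr(m, h, n) = (1 − e^(−h·n/m))^h

for `n` distinct inserted items (with `h = 1` and `n ≪ m` this is ≈ `n/m`).
A query sequence with `d` distinct counted k-mers reports sample `j` when
`100 · found_j / d ≥ T`; `T = 100` is exact containment search.

### Hashing

The hash family is pinned to salted 128-bit blake2b: the digest is split
into two 64-bit lanes `a, b` and the `h` positions are
`(a + i·b) mod m` (double hashing), so one digest evaluation serves any
`h`. The family identifier and the base seed are recorded in every store's
metadata, and an index refuses queries or updates whose parameter tuple
`(m, h, k, alphabet, canonical, hash_id, seed)` differs. Bit-compatibility
with other implementations is a non-goal; within-build determinism is
contractual and tested.

### Alphabets and canonicalization

Nucleotide k-mers are canonicalized by default (each window replaced by the
lexicographic minimum of itself and its reverse complement), making indexing
strand-independent; the flag is configurable and recorded in metadata.
Amino-acid indexing uses the 20 standard residues; windows containing
B, Z, J, U, O, X, `*` or any other character are skipped, because ambiguous
residues cannot be hashed consistently. Input is uppercased before
windowing; skipped-window counts are logged.

### Translated queries

A nucleotide query against an amino-acid index is translated in all six
frames (standard genetic code; stops render `*`, N-containing codons `X`)
and each frame is scored independently — pooling frames would dilute the
coding frame with five spurious ones. Windows containing `*` stay in the
denominator but are never looked up: they are guaranteed absent, which
enforces the suppression argument — in a uniform random frame one of the 3
stop codons among 64 appears about every `round(64/3) = 21` codons, so a
stop-free stretch of ~20 sense codons yields at most `20 − 11 + 1 = 10`
consecutive matchable 11-mers, far below any useful threshold. Windows
containing `X` are excluded from the denominator by default (an ambiguous
base says nothing about presence); a strict mode counts every window.
The threshold comparison is `≥ T`, so `T = 100` is satisfiable and equals
exact search.

## Storage layout

**Matrix store.** Bits are packed along the row axis into uint8 (LSB-first:
row `r` → byte `r >> 3`, bit `r & 7`) — this orientation is what makes the
transpose and per-byte column independence work, so it is pinned and
asserted in tests. Samples are split into `N = ceil(Y / capacity)` batches
with `capacity = floor(mem_limit / ceil(m/8))`; each batch is one zarr
array of shape `(ceil(m/8), batch_size)` with chunk shape `(X/8,
batch_size)`, zstd level 5. `X` is the largest multiple of 8 with
`X/8 · Y ≤ mem_limit`, capped at `m` rounded up to a multiple of 8;
`C = ceil(m/X)`. All plans, parameters, sample names, and the codec are in
a JSON metadata file, so stores are self-describing and round-trip on
reopen.

**Index store.** One zarr array of shape `(m, ceil(Y/8))`: row `r` is the
bit-slice of Bloom row `r`, packed LSB-first along the sample axis; chunks
cover `X` rows (the same slab geometry as the matrix), so building the
index streams one slab at a time: read the matching chunk from every batch,
unpack row-bits, assemble the slab, repack along samples, compress, write.
Trailing pad bits beyond `Y` are zero and excluded from scoring. Queries
decompress at most one slab per (k-mer, hash) and a per-search LRU cache
(byte-bounded) makes repeated rows free, so a query of `q` k-mers touches
at most `q·h` slabs regardless of `N` — instrumented in a test.

**Updates** append samples by widening every slab (unpack old bits, append
the new samples' bits, repack) into a sibling directory that atomically
replaces the store. Existing ordinals never change, no bit ever flips
1 → 0, and the result is query-equivalent to a rebuild over the union —
the only contract, since per-slab rewrite vs. side files is an internal
choice; rewriting keeps constant-probe queries.

**Concurrency.** The build contract is a single shared writable buffer per
batch (or per slab) with workers owning disjoint columns; it is implemented
with a thread pool over a shared numpy buffer, which is zero-copy by
construction. Output is byte-identical for any worker count, verified
file-by-file.

**FAQIndex.** Random access over FASTA/FASTQ records: each row stores
(ordinal, name, sequence byte offset, byte length including line breaks,
base count, wrap width). The sixth field, wrap width, supports offset
arithmetic on wrapped FASTA in the style of `faidx`. Rows are serialized
(canonical field order, JSON) and zlib-compressed, keyed by ordinal in an
embedded SQLite database that supports many concurrent readers; a JSON
metadata file records source path, format, codec, and record count. Offsets
of gzip inputs refer to the decompressed stream (fetch seeks through the
gzip reader). Names are truncated at the first whitespace; FASTQ quality is
discarded (never used); duplicate names are allowed (ordinal is the key).

## Synthetic data

The fixture generator emulates the inputs the pipeline is built for:
collections of protein or DNA sequences as FASTA/FASTQ, one sample per file
or per record, with i.i.d. uniform residues and seeded, byte-reproducible
output. Uniform sequences are the natural null model for the structural
guarantees tested here (zero false negatives, transpose exactness,
plan/worker invariance, FPR calibration, stop-codon suppression) because
those properties are distribution-free. What uniform fixtures do **not**
model is the k-mer sharing, repeat structure, and skewed composition of
real genomes — so passing tests say nothing quantitative about score
distributions between related real samples, only about the correctness and
calibration of the machinery.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen to exercise every
code path (multiple batches, multiple chunks, both alphabets, `h ∈ {1,2}`,
`k ∈ {11,21,31}`) while completing in well under a minute each: filters of
10⁵–10⁶ bits, 5–16 samples, sequences of 150–300 residues, 10⁶ probes for
false-positive calibration. The FPR check compares the empirical
false-positive fraction of never-inserted k-mers with the analytic value
within 3 standard errors, where the standard error combines two sources:
binomial probe sampling (`√(p(1−p)/N)`) and the fluctuation of the realized
filter's occupancy around its expectation (`h·p/q·√(q(1−q)/m)` with
`q = 1 − e^(−hn/m)`, by the delta method on `p = q^h`). Ignoring the second
term would make the test reject a correct implementation for roughly a
third of seeds at `h = 1`, where realization noise dominates.

Degenerate inputs: empty samples keep an all-zero column (with a warning);
queries shorter than `k`, or with zero counted k-mers, emit a warning and
no rows; `m` not divisible by 8 pads the last byte with zero bits that are
excluded everywhere; ties in the output TSV are broken by sample name, and
rows are sorted by (query, frame, descending score, sample) so output is
deterministic.

## Limitations

* No k-mer counting or abundance filtering — presence/absence only.
* No sample deletion and no resizing of `m` after build.
* No minimizers, no hierarchical/tree index, no alternative genetic codes.
* The per-query false-discovery calculation that picks a minimum query
  length for a target per-query FPR is out of scope; the `plan` subcommand
  exposes only the standard per-k-mer Bloom formula.
* Updates rewrite the whole index once per call (linear cost); for frequent
  tiny updates, batch the additions.
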