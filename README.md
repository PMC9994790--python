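# bloomsig

Bit-sliced Bloom filter indexing and thresholded k-mer search for large
collections of amino-acid and nucleotide sequences — including querying a
protein index directly with DNA reads via six-frame translation.

## The problem

Sequence archives have grown past the point where alignment-based search
across thousands of samples is practical. A standard answer is approximate
membership: represent each sample by the **set of k-mers** it contains,
store each set in a Bloom filter, and ask "which samples contain (most of)
this query's k-mers?". Bloom filters guarantee **zero false negatives** and
a tunable false-positive rate, so containment queries are fast and never
miss a truly present sequence.

Most such indexes are nucleotide-only. Protein sequences are conserved over
longer evolutionary distances and synonymous mutations vanish at the protein
level, so `bloomsig` indexes **amino-acid** k-mer sets as well, and lets you
search a protein index with nucleotide queries: the query is translated in
all six reading frames and each frame is scored independently. In the five
biologically wrong frames a stop codon appears about every 21 codons, so at
`k = 11` no spurious frame can string together more than ~10 consecutive
matchable k-mers — random DNA cannot reach a high reporting threshold.

## The data structure

For `Y` samples and Bloom filters of `m` bits with `h` hash functions:

* **Packed Bloom matrix** — an `m × Y` bit matrix; column `j` is sample
  `j`'s Bloom filter. Bits are packed eight-per-byte along the row axis
  (uint8, LSB-first). Samples are built in `N` memory-bounded batches and
  each batch is stored as a zarr array whose chunks cover `X = m/C` rows,
  zstd-compressed — compressing chunks of many columns together compresses
  far better than compressing filters individually.
* **Bit-sliced index** — the exact transpose: an array of `m` cells where
  cell `r` holds row `r` across all `Y` samples, packed along the sample
  axis. A query k-mer needs only its `h` bit-slices AND-ed together, so
  per-k-mer query cost is constant no matter how many batches the matrix
  was built in. New samples can be appended without rebuilding
  (`update_index`), and the result is query-equivalent to a full rebuild.
* **FAQIndex** — a random-access index over FASTA/FASTQ files (plain or
  gzip): ordinal → name, byte offset, byte length, base count, wrap width,
  stored as compressed rows in an embedded SQLite database, so one
  multi-record file can be treated as one-sample-per-record and distributed
  across workers.

A sample is reported when at least `T` percent of the query's distinct
k-mers are found (`T = 100` is exact search). Scores are
`100 · found / counted` per sample (and per frame, for translated queries).

## Worked example

`python examples/build_and_search.py` builds five synthetic protein samples
(`m = 100 000`, `h = 2`, `k = 11`), indexes them, and searches:

```
indexed 5 samples, m=100000 bits, h=2, k=11
exact   T=100  sample_2  100.00%
approx  T=70   sample_2  82.20%
```

The exact query is an indexed sequence, so its own sample scores 100% —
Bloom filters never lose an inserted k-mer. The second query has a 12-residue
corrupted stretch; the k-mers spanning it disappear, the score drops to
82.2%, and the true sample is still reported at `T = 70`.

`python examples/translated_search.py` queries a protein index with DNA:

```
coding read      frame 1  prot_3  100.00%
reverse strand   frame 4  prot_3  100.00%
random DNA at T=75: 0 hits (stop codons suppress all frames)
```

The coding read hits its protein in frame 1; reverse-complementing it moves
the hit to a reverse frame; random DNA finds nothing at `T = 75`.

## Command line

```
bloomsig build    -c config.yml          # packed Bloom matrix
bloomsig index    -c config.yml          # bit-sliced index
bloomsig update   -c config.yml -i DIR   # append new samples
bloomsig search   -i DIR -s SEQ -T 75 -o hits.tsv
bloomsig search   -i DIR -f queries.fa -T 100 -o hits.tsv
bloomsig faqindex -f FILE -o DIR
bloomsig plan     -m 600000000 -h 2 -n 100000000
```

The YAML config carries `k, m, h, sequence_type, canonical, max_memory,
workers, input_mode (per_file | per_record), input_list / input_file,
output_dir, seed`. Results are TSV:
`query_id  frame  sample  score_percent` (frame 0 = untranslated, 1–6 =
translated), sorted deterministically.

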