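"""Size a Bloom filter index before building it.

Prints the analytic false-positive rate for candidate (m, h) at several
fill levels, the uncompressed matrix footprint for a large collection, and
the stop-codon arithmetic behind translated-search suppression.
"""

from bloomsig import (
    FprInputs,
    bloom_fpr,
    expected_stop_spacing,
    max_spurious_run,
    uncompressed_matrix_bits,
)

m, h = 600_000_000, 2
print(f"false-positive rate at m={m:,}, h={h}:")
for n in (10**6, 10**7, 10**8, 3 * 10**8):
    print(f"  n={n:>11,} distinct k-mers  ->  fpr = {bloom_fpr(FprInputs(m, h, n)):.4g}")

bits, tib = uncompressed_matrix_bits(600_000_000, 100_384)
print(f"\nuncompressed matrix for 100,384 samples: {bits:,} bits = {tib} TiB")
print("(chunked zstd compression stores this at a small fraction of that)")

spacing = expected_stop_spacing(3, 64)
run = max_spurious_run(11, spacing - 1)
print(f"\nrandom reading frame: one stop every ~{spacing} codons,")
print(f"so a spurious frame yields at most {run} consecutive matchable 11-mers")
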