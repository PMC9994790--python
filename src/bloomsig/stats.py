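"""Analytic calculators: Bloom false-positive rate, storage footprint, and
stop-codon arithmetic behind the translated-search design.

The standard Bloom approximation for a filter of ``m`` bits, ``h`` hash
functions and ``n`` distinct inserted items gives a false-positive
probability of ``(1 - exp(-h*n/m))**h``; with ``h = 1`` and ``n << m`` this
reduces to ``~ n/m``.  Storage of the uncompressed Bloom filter matrix is
simply ``m * Y`` bits for ``Y`` samples.

Under a uniform random codon model the standard genetic code (3 stop codons
of 64) yields a stop about every 21 codons, so a stop-free stretch of ~20
sense codons in a spurious reading frame supports at most
``20 - k + 1 = 10`` consecutive matchable k-mers at ``k = 11`` — the reason
non-coding frames cannot reach a high search threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple


@dataclass(frozen=True)
class FprInputs:
    """Inputs to the Bloom false-positive approximation."""

    m: int  # filter size in bits
    h: int  # hash functions per item
    n: int  # distinct items inserted

    def __post_init__(self):
        if self.m < 1 or self.h < 1 or self.n < 0:
            raise ValueError("need m >= 1, h >= 1, n >= 0")


def bloom_fpr(inp: FprInputs) -> float:
    """``(1 - e^(-h*n/m))^h``, the standard Bloom false-positive rate."""
    return (1.0 - math.exp(-inp.h * inp.n / inp.m)) ** inp.h


def uncompressed_matrix_bits(m: int, Y: int) -> Tuple[int, float]:
    """Uncompressed Bloom matrix footprint: total bits and TiB (2 decimals).

    TiB uses binary units (1024**4 bytes).
    """
    if m < 1 or Y < 1:
        raise ValueError("need m >= 1 and Y >= 1")
    bits = m * Y
    tib = round(bits / 8 / 1024**4, 2)
    return bits, tib


def expected_stop_spacing(stop_count: int, codon_count: int) -> int:
    """Expected codons per stop codon under a uniform random codon model."""
    if stop_count < 1:
        raise ValueError("stop_count must be >= 1 (no stops means unbounded spacing)")
    if codon_count < stop_count:
        raise ValueError("stop_count cannot exceed codon_count")
    return round(codon_count / stop_count)


def max_spurious_run(k: int, stop_free_len: int) -> int:
    """Longest run of k-length windows inside a stop-free translated stretch."""
    if k < 1 or stop_free_len < 0:
        raise ValueError("need k >= 1 and stop_free_len >= 0")
    return max(0, stop_free_len - k + 1)
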