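"""K-mer extraction, translation, and hashing.

A sequence collection is indexed by the set of length-``k`` windows of its
sequences.  Nucleotide windows may be canonicalized (replaced by the
lexicographic minimum of the window and its reverse complement) so that
indexing is strand-independent.  Each k-mer is mapped to ``h`` positions in an
``m``-bit Bloom filter by double hashing: two independent 64-bit lanes of a
single keyed blake2b digest give ``position_i = (a + i*b) mod m``.

Nucleotide queries can be run against an amino-acid index via six-frame
translation with the standard genetic code; stop codons render as ``*`` and
codons containing ``N`` as ``X``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, List

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGT")
AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code, codons enumerated in TCAG order.
_BASES = "TCAG"
_AA_BY_CODON = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(
        ((x, y, z) for x in _BASES for y in _BASES for z in _BASES), _AA_BY_CODON
    )
}

HASH_ID = "blake2b-128"


@dataclass(frozen=True)
class KmerScheme:
    """How sequences are decomposed into k-mers.

    Parameters
    ----------
    k:
        Window length; ``k >= 1``.
    alphabet:
        ``"nucleotide"`` or ``"amino_acid"``.
    canonical:
        For nucleotide schemes, replace each window by
        ``min(window, reverse_complement(window))``.  Must be False for
        amino-acid schemes (proteins have no strand).
    """

    k: int
    alphabet: str
    canonical: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.alphabet not in ("nucleotide", "amino_acid"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "amino_acid" and self.canonical:
            raise ValueError("canonical k-mers are undefined for amino acids")

    @property
    def letters(self) -> frozenset:
        if self.alphabet == "nucleotide":
            return NUCLEOTIDE_ALPHABET
        return AMINO_ACID_ALPHABET


@dataclass(frozen=True)
class BloomParams:
    """The parameter tuple that defines an index.

    An index built with one tuple refuses queries or updates made with a
    different one; the full tuple is recorded in every store's metadata.

    ``m`` is the Bloom filter size in bits, ``h`` the number of hash
    functions applied to every k-mer, ``seed`` the base hash seed, and
    ``hash_id`` pins the hash family.
    """

    m: int
    h: int
    scheme: KmerScheme
    hash_id: str = HASH_ID
    seed: int = 0

    def __post_init__(self):
        if self.m < 8:
            raise ValueError(f"m must be >= 8, got {self.m}")
        if self.h < 1:
            raise ValueError(f"h must be >= 1, got {self.h}")
        if self.hash_id != HASH_ID:
            raise ValueError(f"unsupported hash family {self.hash_id!r}")

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "h": self.h,
            "k": self.scheme.k,
            "alphabet": self.scheme.alphabet,
            "canonical": self.scheme.canonical,
            "hash_id": self.hash_id,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BloomParams":
        return cls(
            m=d["m"],
            h=d["h"],
            scheme=KmerScheme(k=d["k"], alphabet=d["alphabet"], canonical=d["canonical"]),
            hash_id=d.get("hash_id", HASH_ID),
            seed=d.get("seed", 0),
        )


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (``N`` maps to ``N``)."""
    if not set(sequence) <= {"A", "C", "G", "T", "N"}:
        bad = sorted(set(sequence) - {"A", "C", "G", "T", "N"})
        raise ValueError(f"invalid nucleotide characters: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Lexicographic minimum of a nucleotide k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def extract_kmers(sequence: str, scheme: KmerScheme) -> List[str]:
    """All valid length-``k`` windows of ``sequence``, in order.

    The input is uppercased first.  Windows containing a character outside
    the scheme's alphabet are skipped (the skip count is logged); short or
    empty sequences yield an empty list.
    """
    seq = sequence.upper()
    k = scheme.k
    n_windows = len(seq) - k + 1
    if n_windows <= 0:
        return []
    letters = scheme.letters
    # last_bad[i] tracking: a window [i, i+k) is valid iff no invalid char
    # occurs at positions i..i+k-1.
    out: List[str] = []
    skipped = 0
    last_bad = -1
    for i, ch in enumerate(seq):
        if ch not in letters:
            last_bad = i
        start = i - k + 1
        if start < 0:
            continue
        if last_bad >= start:
            skipped += 1
            continue
        w = seq[start : i + 1]
        if scheme.canonical:
            w = canonicalize(w)
        out.append(w)
    if skipped:
        logger.debug("skipped %d windows containing out-of-alphabet characters", skipped)
    return out


def six_frame_translate(sequence: str) -> List[str]:
    """Translate a nucleotide string in all six reading frames.

    Frames 1-3 read the forward strand at offsets 0, 1, 2; frames 4-6 read
    the reverse complement at offsets 0, 1, 2.  Stop codons render as ``*``,
    codons containing ``N`` as ``X``; trailing 1-2 nt of a frame are dropped.
    """
    seq = sequence.upper()
    rc = reverse_complement(seq)  # also validates characters
    frames = []
    for strand in (seq, rc):
        for offset in range(3):
            n_codons = (len(strand) - offset) // 3
            aa = []
            for c in range(n_codons):
                codon = strand[offset + 3 * c : offset + 3 * c + 3]
                aa.append(GENETIC_CODE.get(codon, "X"))
            frames.append("".join(aa))
    return frames


def hash_positions(kmer: str, params: BloomParams) -> List[int]:
    """The ``h`` Bloom filter positions of a k-mer, each in ``[0, m)``.

    Double hashing over two 64-bit lanes of one keyed blake2b digest;
    duplicates are possible and not deduplicated.
    """
    digest = hashlib.blake2b(
        kmer.encode("ascii"),
        digest_size=16,
        salt=params.seed.to_bytes(8, "little", signed=False),
    ).digest()
    a = int.from_bytes(digest[:8], "little")
    b = int.from_bytes(digest[8:], "little")
    m = params.m
    return [(a + i * b) % m for i in range(params.h)]


def distinct_kmers(sequences: Iterable[str], scheme: KmerScheme) -> List[str]:
    """Order-preserving distinct k-mers over a collection of sequences."""
    seen = dict.fromkeys(
        w for seq in sequences for w in extract_kmers(seq, scheme)
    )
    return list(seen)
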