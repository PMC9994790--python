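"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bloomsig import (
    BloomParams,
    KmerScheme,
    build_index,
    build_matrix,
    extract_kmers,
    hash_positions,
)
AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


def random_seq(rng: np.random.Generator, length: int, letters: str = AA) -> str:
    return "".join(letters[i] for i in rng.integers(0, len(letters), size=length))


def random_kmer_set(rng: np.random.Generator, n: int, k: int, letters: str = AA):
    """n distinct random k-mers."""
    out = {}
    while len(out) < n:
        out.setdefault(random_seq(rng, k, letters), None)
    return list(out)


def naive_bit_matrix(samples, params: BloomParams) -> np.ndarray:
    """Brute-force unpacked (m x Y) bit matrix from hash positions."""
    mat = np.zeros((params.m, len(samples)), dtype=np.uint8)
    for j, (_, kmers) in enumerate(samples):
        for w in kmers:
            for p in hash_positions(w, params):
                mat[p, j] = 1
    return mat


def build_sample_set(rng, n_samples, seq_len, scheme, letters=AA):
    """Samples as (name, list-of-kmers) pairs from random sequences."""
    seqs = [(f"s{j}", random_seq(rng, seq_len, letters)) for j in range(n_samples)]
    samples = [(n, extract_kmers(s, scheme)) for n, s in seqs]
    return seqs, samples


@pytest.fixture
def aa_scheme():
    return KmerScheme(k=11, alphabet="amino_acid")


@pytest.fixture
def small_protein_index(tmp_path, aa_scheme):
    """6 random proteins indexed at m=20000, h=2, k=11, plus the inputs."""
    rng = np.random.default_rng(11)
    params = BloomParams(m=20000, h=2, scheme=aa_scheme)
    seqs, samples = build_sample_set(rng, 6, 150, aa_scheme)
    mat = build_matrix(samples, params, tmp_path / "mat", mem_limit=1 << 20)
    idx = build_index(mat, tmp_path / "idx")
    return {"index": idx, "matrix": mat, "seqs": seqs, "samples": samples,
            "params": params}
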