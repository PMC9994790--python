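"""Packing, memory planning, and packed Bloom matrix construction."""

import math

import numpy as np
import pytest

from bloomsig import (
    BloomParams,
    KmerScheme,
    build_matrix,
    pack_bits,
    plan_batches,
    plan_chunks,
    unpack_bits,
)
from bloomsig.bloom_matrix import get_bit
from bloomsig.errors import ConfigurationError
from bloomsig.kmers import hash_positions

from conftest import build_sample_set, naive_bit_matrix, random_kmer_set

AA_SCHEME = KmerScheme(k=11, alphabet="amino_acid")


@pytest.mark.parametrize(
    "bits,byte",
    [([1, 0, 0, 0, 0, 0, 0, 0], 0x01),
     ([0] * 8, 0x00),
     ([1] * 8, 0xFF),
     ([0, 0, 0, 0, 0, 0, 0, 1], 0x80)],
)
def test_pack_bits_lsb_first(bits, byte):
    assert pack_bits(bits) == byte
    assert unpack_bits(byte) == bits


def test_pack_unpack_roundtrip_exhaustive():
    for b in range(256):
        assert pack_bits(unpack_bits(b)) == b


def test_pack_bits_validates():
    with pytest.raises(ValueError):
        pack_bits([1, 0, 1])
    with pytest.raises(ValueError):
        pack_bits([2, 0, 0, 0, 0, 0, 0, 0])


def test_plan_batches_arithmetic():
    plan = plan_batches(Y=100, m=8000, mem_limit=40 * 1000)
    assert plan.N == 3
    assert list(plan.batch_sizes) == [40, 40, 20]
    assert sum(plan.batch_sizes) == 100


def test_plan_batches_single_batch_when_all_fit():
    assert plan_batches(Y=8, m=8000, mem_limit=10**6).N == 1


def test_plan_batches_infeasible_budget():
    with pytest.raises(ConfigurationError):
        plan_batches(Y=10, m=8000, mem_limit=999)


def test_plan_chunks_arithmetic():
    plan = plan_chunks(m=8000, Y=10, mem_limit=1000)
    assert (plan.X, plan.C) == (800, 10)


def test_plan_chunks_rounding_invariants():
    plan = plan_chunks(m=100, Y=3, mem_limit=10)
    assert plan.X % 8 == 0
    assert plan.C * plan.X >= 100
    ranges = plan.row_ranges
    assert ranges[0][0] == 0 and ranges[-1][1] == 100
    assert all(a[1] == b[0] for a, b in zip(ranges, ranges[1:]))


def test_plan_chunks_single_chunk_for_huge_budget():
    plan = plan_chunks(m=1001, Y=1, mem_limit=10**9)
    assert plan.C == 1 and plan.X == 1008  # m rounded up to a multiple of 8


def test_single_kmer_sets_at_most_h_bits(tmp_path):
    params = BloomParams(m=4096, h=2, scheme=AA_SCHEME)
    store = build_matrix([("s0", ["MKLVNQWERTY"])], params, tmp_path / "m",
                         mem_limit=1 << 16)
    set_bits = [r for r in range(4096) if store.get_bit(r, 0)]
    positions = set(hash_positions("MKLVNQWERTY", params))
    assert set(set_bits) == positions
    assert 1 <= len(set_bits) <= 2


def test_empty_sample_keeps_all_zero_column(tmp_path, caplog):
    params = BloomParams(m=512, h=2, scheme=AA_SCHEME)
    with caplog.at_level("WARNING"):
        store = build_matrix([("empty", []), ("full", ["AAAAAAAAAAA"])],
                             params, tmp_path / "m", mem_limit=1 << 16)
    assert "zero valid k-mers" in caplog.text
    assert all(store.get_bit(r, 0) == 0 for r in range(512))


def test_duplicate_sample_names_rejected(tmp_path):
    params = BloomParams(m=512, h=1, scheme=AA_SCHEME)
    with pytest.raises(ValueError, match="duplicate"):
        build_matrix([("a", []), ("a", [])], params, tmp_path / "m")


def _store_files(path):
    return sorted(p.relative_to(path) for p in path.rglob("*") if p.is_file())


def test_worker_count_does_not_change_bytes(tmp_path):
    rng = np.random.default_rng(21)
    params = BloomParams(m=8192, h=2, scheme=AA_SCHEME)
    _, samples = build_sample_set(rng, 5, 120, AA_SCHEME)
    s1 = build_matrix(samples, params, tmp_path / "w1", mem_limit=1 << 16, workers=1)
    s4 = build_matrix(samples, params, tmp_path / "w4", mem_limit=1 << 16, workers=4)
    files1, files4 = _store_files(s1.path), _store_files(s4.path)
    assert files1 == files4
    for rel in files1:
        assert (s1.path / rel).read_bytes() == (s4.path / rel).read_bytes()


def test_get_bit_matches_naive_oracle(tmp_path):
    rng = np.random.default_rng(31)
    params = BloomParams(m=5000, h=2, scheme=AA_SCHEME)
    samples = [(f"s{j}", random_kmer_set(rng, 200, 11)) for j in range(8)]
    store = build_matrix(samples, params, tmp_path / "m", mem_limit=2000)
    assert store.batch_plan.N > 1  # exercise multi-batch reads
    oracle = naive_bit_matrix(samples, params)
    rows = rng.integers(0, 5000, size=300)
    cols = rng.integers(0, 8, size=300)
    for r, j in zip(rows, cols):
        assert store.get_bit(int(r), int(j)) == oracle[r, j]
    with pytest.raises(IndexError):
        store.get_bit(5000, 0)
    with pytest.raises(IndexError):
        store.get_bit(0, 8)


def test_metadata_roundtrip(tmp_path):
    from bloomsig import PackedBloomMatrixStore

    params = BloomParams(m=1024, h=3, scheme=KmerScheme(k=21, alphabet="nucleotide",
                                                        canonical=True), seed=5)
    store = build_matrix([("a", ["A" * 21]), ("b", [])], params, tmp_path / "m",
                         mem_limit=1 << 16)
    reopened = PackedBloomMatrixStore(tmp_path / "m")
    assert reopened.params == params
    assert reopened.sample_names == ["a", "b"]
    assert reopened.batch_plan == store.batch_plan
    assert reopened.chunk_plan == store.chunk_plan


def test_column_occupancy_matches_theory(tmp_path):
    """Fill fraction of a column after n distinct insertions tracks
    1 - e^(-h n / m) within 3 standard errors."""
    m, h, n = 100_000, 2, 10_000
    rng = np.random.default_rng(41)
    params = BloomParams(m=m, h=h, scheme=AA_SCHEME)
    kmers = random_kmer_set(rng, n, 11)
    store = build_matrix([("s", kmers)], params, tmp_path / "m", mem_limit=1 << 20)
    packed = store.read_batch_rows(0, 0, (m + 7) // 8)[:, 0]
    occ = int(np.unpackbits(packed, bitorder="little", count=m).sum())
    p = 1 - math.exp(-h * n / m)
    se = math.sqrt(p * (1 - p) / m)
    assert abs(occ / m - p) < 3 * se
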