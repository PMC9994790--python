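"""Column-oriented packed Bloom-filter matrix construction and storage.

The matrix has one column per sample and one row per Bloom filter bit:
column ``j`` is sample ``j``'s Bloom filter of length ``m``.  Bits are packed
eight-per-byte along the row axis (LSB-first: row ``r`` lives in byte
``r >> 3``, bit ``r & 7``), so a column occupies ``ceil(m/8)`` bytes.

Construction is memory-bounded twice over:

* samples are split into ``N`` batches so a batch's packed columns fit the
  memory budget;
* each batch's packed matrix is chunked into ``C`` row blocks of ``X = m/C``
  rows, each compressed (zstd) and persisted as one chunk of a zarr array,
  so the rows covering any bit range can later be loaded across all batches
  simultaneously.

Within a batch the packed matrix is one shared buffer that several workers
fill concurrently, each owning a disjoint subset of columns; because packing
is along rows, no two workers ever touch the same byte, and the output is
byte-identical for any worker count.
"""

from __future__ import annotations

import json
import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import zarr

from .errors import ConfigurationError, StoreCorruptionError
from .kmers import BloomParams, hash_positions

logger = logging.getLogger(__name__)

_META_NAME = "metadata.json"
_FORMAT_VERSION = 1
DEFAULT_CODEC = ("zstd", 5)


def pack_bits(bits: Sequence[int]) -> int:
    """Pack exactly 8 binary values into one byte, LSB-first."""
    if len(bits) != 8:
        raise ValueError(f"need exactly 8 bits, got {len(bits)}")
    if any(b not in (0, 1) for b in bits):
        raise ValueError("bits must be 0 or 1")
    return int(np.packbits(np.asarray(bits, dtype=np.uint8), bitorder="little")[0])


def unpack_bits(byte: int) -> List[int]:
    """Inverse of :func:`pack_bits`."""
    return list(np.unpackbits(np.uint8(byte), bitorder="little"))


def packed_rows(m: int) -> int:
    return (m + 7) // 8


@dataclass(frozen=True)
class BatchPlan:
    """How the Y samples are split into batches that fit in memory."""

    Y: int
    batch_sizes: Tuple[int, ...]
    mem_limit: int

    @property
    def N(self) -> int:
        return len(self.batch_sizes)

    @property
    def offsets(self) -> List[int]:
        """Global column offset of each batch."""
        out, acc = [], 0
        for s in self.batch_sizes:
            out.append(acc)
            acc += s
        return out


@dataclass(frozen=True)
class ChunkPlan:
    """Row chunking: C blocks of X rows (X a multiple of 8) covering [0, m)."""

    m: int
    X: int
    C: int

    @property
    def row_ranges(self) -> List[Tuple[int, int]]:
        return [(lo, min(lo + self.X, self.m)) for lo in range(0, self.m, self.X)]


def plan_batches(Y: int, m: int, mem_limit: int) -> BatchPlan:
    """Split Y samples into batches whose packed columns fit ``mem_limit`` bytes."""
    col_bytes = packed_rows(m)
    if mem_limit < col_bytes:
        raise ConfigurationError(
            f"memory budget {mem_limit} B is below one packed Bloom column "
            f"({col_bytes} B); raise the budget or shrink m"
        )
    capacity = mem_limit // col_bytes
    n_batches = math.ceil(Y / capacity) if Y else 1
    sizes = [capacity] * (Y // capacity) + ([Y % capacity] if Y % capacity else [])
    if not sizes:
        sizes = [Y]
    return BatchPlan(Y=Y, batch_sizes=tuple(sizes), mem_limit=mem_limit)


def plan_chunks(m: int, Y: int, mem_limit: int) -> ChunkPlan:
    """Choose X = rows per chunk so X/8 bytes x Y samples fit ``mem_limit``."""
    if mem_limit < Y:
        raise ConfigurationError(
            f"memory budget {mem_limit} B cannot hold one packed row block for "
            f"{Y} samples; need at least {Y} B"
        )
    X = 8 * (mem_limit // Y) if Y else 8 * packed_rows(m)
    X = min(X, 8 * packed_rows(m))  # cap at m rounded up to a multiple of 8
    C = math.ceil(m / X)
    return ChunkPlan(m=m, X=X, C=C)


class PackedBloomMatrixStore:
    """On-disk, per-batch, column-oriented packed Bloom filter matrix.

    Directory layout: ``metadata.json`` plus one zarr array per batch
    (``batch_00000``, ...), each of shape ``(ceil(m/8), batch_size)`` uint8
    with chunk shape ``(X/8, batch_size)``.
    """

    def __init__(self, path):
        self.path = Path(path)
        meta_path = self.path / _META_NAME
        if not meta_path.exists():
            raise StoreCorruptionError(f"no matrix metadata at {meta_path}")
        with open(meta_path) as fh:
            self.metadata = json.load(fh)
        self.params = BloomParams.from_dict(self.metadata["params"])
        self.sample_names: List[str] = self.metadata["sample_names"]
        self.batch_plan = BatchPlan(
            Y=self.metadata["Y"],
            batch_sizes=tuple(self.metadata["batch_sizes"]),
            mem_limit=self.metadata["mem_limit"],
        )
        self.chunk_plan = ChunkPlan(
            m=self.params.m, X=self.metadata["X"], C=self.metadata["C"]
        )
        self.codec = tuple(self.metadata["codec"])

    @property
    def m(self) -> int:
        return self.params.m

    @property
    def Y(self) -> int:
        return self.batch_plan.Y

    def _batch_array(self, b: int) -> zarr.Array:
        name = f"batch_{b:05d}"
        arr_path = self.path / name
        if not arr_path.exists():
            lo = self.batch_plan.offsets[b]
            raise StoreCorruptionError(
                f"missing chunk array for batch {b} (columns {lo}..)"
            )
        return zarr.open_array(str(arr_path), mode="r")

    def read_batch_rows(self, b: int, byte_lo: int, byte_hi: int) -> np.ndarray:
        """Packed bytes ``[byte_lo, byte_hi)`` of every column in batch ``b``."""
        return self._batch_array(b)[byte_lo:byte_hi, :]

    def get_bit(self, row: int, sample: int) -> int:
        """One logical matrix bit, read through chunk decompression."""
        if not 0 <= row < self.m:
            raise IndexError(f"row {row} out of range [0, {self.m})")
        if not 0 <= sample < self.Y:
            raise IndexError(f"sample {sample} out of range [0, {self.Y})")
        b = 0
        local = sample
        for size in self.batch_plan.batch_sizes:
            if local < size:
                break
            local -= size
            b += 1
        byte = int(self._batch_array(b)[row >> 3, local])
        return (byte >> (row & 7)) & 1


def _fill_column(buf: np.ndarray, col: int, kmer_source: Iterable[str],
                 params: BloomParams) -> int:
    """Set the bits of one sample's Bloom filter in the shared packed buffer."""
    n = 0
    for kmer in kmer_source:
        for p in hash_positions(kmer, params):
            buf[p >> 3, col] |= np.uint8(1 << (p & 7))
        n += 1
    return n


def build_matrix(
    samples: Sequence[Tuple[str, Iterable[str]]],
    params: BloomParams,
    out,
    mem_limit: int = 1 << 30,
    workers: int = 1,
    batch_plan: BatchPlan | None = None,
    chunk_plan: ChunkPlan | None = None,
    codec: Tuple[str, int] = DEFAULT_CODEC,
) -> PackedBloomMatrixStore:
    """Build the packed Bloom filter matrix for a list of (name, k-mer source).

    For every k-mer ``w`` of sample ``j`` and every ``p`` in
    ``hash_positions(w)``, bit ``(p, j)`` is set; all other bits are zero.
    The store is byte-identical regardless of ``workers``.
    """
    names = [name for name, _ in samples]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sample names: {dupes}")
    Y = len(samples)
    if batch_plan is None:
        batch_plan = plan_batches(Y, params.m, mem_limit)
    if chunk_plan is None:
        chunk_plan = plan_chunks(params.m, max(Y, 1), mem_limit)
    if sum(batch_plan.batch_sizes) != Y:
        raise ValueError("batch plan does not cover the sample list")

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    pr = packed_rows(params.m)
    chunk_bytes = chunk_plan.X // 8

    offset = 0
    for b, bsz in enumerate(batch_plan.batch_sizes):
        buf = np.zeros((pr, bsz), dtype=np.uint8)
        batch = samples[offset : offset + bsz]
        if workers <= 1 or bsz <= 1:
            for j, (name, source) in enumerate(batch):
                if _fill_column(buf, j, source, params) == 0:
                    logger.warning("sample %r has zero valid k-mers; column is all-zero", name)
        else:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futs = {
                    pool.submit(_fill_column, buf, j, source, params): name
                    for j, (name, source) in enumerate(batch)
                }
                for fut, name in futs.items():
                    if fut.result() == 0:
                        logger.warning(
                            "sample %r has zero valid k-mers; column is all-zero", name
                        )
        arr = zarr.create_array(
            store=str(out / f"batch_{b:05d}"),
            shape=(pr, bsz),
            chunks=(min(chunk_bytes, pr), max(bsz, 1)),
            dtype="uint8",
            compressors=zarr.codecs.ZstdCodec(level=codec[1]),
            overwrite=True,
        )
        arr[:] = buf
        logger.info("batch %d/%d written (%d samples)", b + 1, batch_plan.N, bsz)
        offset += bsz

    metadata = {
        "format_version": _FORMAT_VERSION,
        "params": params.to_dict(),
        "sample_names": names,
        "Y": Y,
        "batch_sizes": list(batch_plan.batch_sizes),
        "mem_limit": batch_plan.mem_limit,
        "X": chunk_plan.X,
        "C": chunk_plan.C,
        "codec": list(codec),
    }
    with open(out / _META_NAME, "w") as fh:
        json.dump(metadata, fh, indent=1)
    return PackedBloomMatrixStore(out)


def get_bit(store: PackedBloomMatrixStore, row: int, sample: int) -> int:
    return store.get_bit(row, sample)
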