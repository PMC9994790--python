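"""Row-oriented (bit-sliced) index over the packed Bloom filter matrix.

The index is the exact transpose of the matrix, reorganised for queries: an
array of ``m`` cells where cell ``r`` holds row ``r``'s bits across all ``Y``
samples (a *bit-slice*), packed LSB-first along the sample axis into
``ceil(Y/8)`` bytes.  Looking up one k-mer touches ``h`` slices regardless of
how many batches the matrix was built in, so per-k-mer query cost is constant.

Construction processes rows in slabs of ``X = m/C`` rows: the chunk covering
those rows is read from every batch, unpacked to bits, written into a shared
slab buffer (workers own disjoint column ranges), repacked along the sample
axis, compressed and persisted.  Updates append new samples by widening every
slab; existing sample ordinals never change and no bit ever flips 1 -> 0.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import tempfile
from collections import OrderedDict
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import zarr

from .bloom_matrix import (
    DEFAULT_CODEC,
    BatchPlan,
    ChunkPlan,
    PackedBloomMatrixStore,
    _fill_column,
    packed_rows,
)
from .errors import CompatibilityError, StoreCorruptionError
from .kmers import BloomParams

logger = logging.getLogger(__name__)

_META_NAME = "metadata.json"
_ARRAY_NAME = "slices"
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class BitSlice:
    """One Bloom row's presence bits across all Y samples."""

    row: int
    bits: np.ndarray  # uint8 vector of length Y, values in {0, 1}


class SlabCache:
    """Per-search LRU cache of decompressed slabs, bounded by a byte budget."""

    def __init__(self, max_bytes: int = 256 << 20):
        self.max_bytes = max_bytes
        self._slabs: "OrderedDict[int, np.ndarray]" = OrderedDict()
        self._bytes = 0

    def get(self, slab: int):
        if slab in self._slabs:
            self._slabs.move_to_end(slab)
            return self._slabs[slab]
        return None

    def put(self, slab: int, data: np.ndarray):
        self._slabs[slab] = data
        self._bytes += data.nbytes
        while self._bytes > self.max_bytes and len(self._slabs) > 1:
            _, old = self._slabs.popitem(last=False)
            self._bytes -= old.nbytes


class IndexStore:
    """On-disk bit-sliced index: ``metadata.json`` + one chunked zarr array
    of shape ``(m, ceil(Y/8))`` with slab-sized chunks."""

    def __init__(self, path):
        self.path = Path(path)
        meta_path = self.path / _META_NAME
        if not meta_path.exists():
            raise StoreCorruptionError(f"no index metadata at {meta_path}")
        with open(meta_path) as fh:
            self.metadata = json.load(fh)
        self.params = BloomParams.from_dict(self.metadata["params"])
        self.sample_names: List[str] = self.metadata["sample_names"]
        self.Y: int = self.metadata["Y"]
        self.slab_plan = ChunkPlan(
            m=self.params.m, X=self.metadata["X"], C=self.metadata["C"]
        )
        self.codec = tuple(self.metadata["codec"])
        self._arr = zarr.open_array(str(self.path / _ARRAY_NAME), mode="r")

    @property
    def m(self) -> int:
        return self.params.m

    @property
    def packed_cols(self) -> int:
        return (self.Y + 7) // 8

    def check_params(self, other: BloomParams):
        if other != self.params:
            raise CompatibilityError(
                f"Bloom parameters mismatch: index has {self.params.to_dict()}, "
                f"got {other.to_dict()}"
            )

    def packed_row(self, row: int, cache: SlabCache | None = None) -> np.ndarray:
        """Sample-packed bytes of one bit-slice (``ceil(Y/8)`` uint8 values)."""
        if not 0 <= row < self.m:
            raise IndexError(f"row {row} out of range [0, {self.m})")
        X = self.slab_plan.X
        slab = row // X
        data = cache.get(slab) if cache is not None else None
        if data is None:
            lo = slab * X
            hi = min(lo + X, self.m)
            data = self._arr[lo:hi, :]
            if cache is not None:
                cache.put(slab, data)
        return data[row - slab * X]

    def get_bit_slice(self, row: int, cache: SlabCache | None = None) -> BitSlice:
        packed = self.packed_row(row, cache)
        bits = np.unpackbits(packed, bitorder="little", count=self.Y)
        return BitSlice(row=row, bits=bits)


def _write_index_store(
    out: Path,
    params: BloomParams,
    sample_names: Sequence[str],
    slab_plan: ChunkPlan,
    codec: Tuple[str, int],
    slab_source,
    workers_note: str = "",
) -> IndexStore:
    """Persist slabs yielded by ``slab_source`` as (row_lo, packed_slab)."""
    out.mkdir(parents=True, exist_ok=True)
    Y = len(sample_names)
    pc = (Y + 7) // 8
    arr = zarr.create_array(
        store=str(out / _ARRAY_NAME),
        shape=(params.m, max(pc, 1)),
        chunks=(min(slab_plan.X, params.m), max(pc, 1)),
        dtype="uint8",
        compressors=zarr.codecs.ZstdCodec(level=codec[1]),
        overwrite=True,
    )
    for lo, packed_slab in slab_source:
        arr[lo : lo + packed_slab.shape[0], :] = packed_slab
    metadata = {
        "format_version": _FORMAT_VERSION,
        "params": params.to_dict(),
        "sample_names": list(sample_names),
        "Y": Y,
        "X": slab_plan.X,
        "C": slab_plan.C,
        "codec": list(codec),
    }
    with open(out / _META_NAME, "w") as fh:
        json.dump(metadata, fh, indent=1)
    return IndexStore(out)


def _matrix_slab_bits(
    matrix: PackedBloomMatrixStore, lo: int, hi: int, workers: int
) -> np.ndarray:
    """Unpacked bits of matrix rows [lo, hi) across all samples."""
    nrows = hi - lo
    Y = matrix.Y
    bits = np.zeros((nrows, Y), dtype=np.uint8)

    def fill(b: int, col_off: int):
        packed = matrix.read_batch_rows(b, lo // 8, (hi + 7) // 8)
        unpacked = np.unpackbits(packed, axis=0, bitorder="little")[:nrows, :]
        bits[:, col_off : col_off + unpacked.shape[1]] = unpacked

    jobs = list(zip(range(matrix.batch_plan.N), matrix.batch_plan.offsets))
    if workers <= 1 or len(jobs) <= 1:
        for b, off in jobs:
            fill(b, off)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(lambda jo: fill(*jo), jobs))
    return bits


def build_index(
    matrix: PackedBloomMatrixStore,
    out,
    mem_limit: int | None = None,
    workers: int = 1,
) -> IndexStore:
    """Transpose a packed Bloom matrix into a bit-sliced index.

    Logical content is exactly the matrix transpose; output is byte-identical
    for any worker count.
    """
    slab_plan = matrix.chunk_plan

    def slabs():
        for lo, hi in slab_plan.row_ranges:
            bits = _matrix_slab_bits(matrix, lo, hi, workers)
            yield lo, np.packbits(bits, axis=1, bitorder="little")

    return _write_index_store(
        Path(out), matrix.params, matrix.sample_names, slab_plan,
        matrix.codec, slabs(),
    )


def update_index(
    index: IndexStore,
    new_samples: Sequence[Tuple[str, Iterable[str]]],
    workers: int = 1,
) -> IndexStore:
    """Append new samples to an existing index.

    The result is query-equivalent to rebuilding over the union; existing
    sample ordinals are unchanged.  New sample names must be disjoint from
    the existing ones and the Bloom parameters are taken from the index.
    """
    new_names = [name for name, _ in new_samples]
    if len(set(new_names)) != len(new_names):
        raise ValueError("duplicate names among new samples")
    clash = set(new_names) & set(index.sample_names)
    if clash:
        raise ValueError(f"sample names already present in index: {sorted(clash)}")
    if not new_samples:
        return index

    params = index.params
    pr = packed_rows(params.m)
    n_new = len(new_samples)
    # Packed columns of the new samples, built in memory (row-axis packing).
    new_cols = np.zeros((pr, n_new), dtype=np.uint8)
    for j, (name, source) in enumerate(new_samples):
        if _fill_column(new_cols, j, source, params) == 0:
            logger.warning("sample %r has zero valid k-mers; column is all-zero", name)

    all_names = list(index.sample_names) + new_names
    old_Y = index.Y
    X = index.slab_plan.X

    def slabs():
        for lo, hi in index.slab_plan.row_ranges:
            nrows = hi - lo
            old_packed = index._arr[lo:hi, :]
            old_bits = np.unpackbits(old_packed, axis=1, bitorder="little")[:, :old_Y]
            new_bits = np.unpackbits(
                new_cols[lo // 8 : (hi + 7) // 8, :], axis=0, bitorder="little"
            )[:nrows, :]
            merged = np.concatenate([old_bits, new_bits], axis=1)
            yield lo, np.packbits(merged, axis=1, bitorder="little")

    tmp = Path(tempfile.mkdtemp(prefix="idx_update_", dir=index.path.parent))
    try:
        _write_index_store(tmp, params, all_names, index.slab_plan, index.codec, slabs())
        old_path = index.path
        backup = Path(str(old_path) + ".old")
        os.replace(old_path, backup)
        os.replace(tmp, old_path)
        shutil.rmtree(backup)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    logger.info("index updated: %d -> %d samples", old_Y, len(all_names))
    return IndexStore(old_path)


def get_bit_slice(index: IndexStore, row: int) -> BitSlice:
    return index.get_bit_slice(row)
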