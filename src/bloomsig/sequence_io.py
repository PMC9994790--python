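"""FASTA/FASTQ reading, random-access indexing, and synthetic fixtures.

The random-access index ("FAQIndex") maps each record ordinal to its name,
the byte offset where its sequence data begins, the byte length of that data
(line breaks included), the residue count, and the line-wrap width.  Rows are
serialized, compressed, and stored in an embedded SQLite database so the same
index can be read by many processes at once; offsets of gzip inputs refer to
the decompressed stream.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import os
import sqlite3
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .errors import SequenceParseError, StoreCorruptionError

logger = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"
_DB_NAME = "faqindex.sqlite"
_META_NAME = "metadata.json"
_FORMAT_VERSION = 1

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
NT_LETTERS = "ACGT"


@dataclass(frozen=True)
class SequenceRecord:
    """Random-access metadata for one sequence record."""

    ordinal: int
    name: str
    offset: int          # byte position where sequence data begins
    byte_length: int     # bytes spanned by the sequence data incl. line breaks
    base_count: int      # number of residues/bases
    bases_per_line: int  # line-wrap width (0 when the record has no bases)


def is_gzip(path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def _open_text_stream(path) -> io.BufferedReader:
    """Binary stream over the (decompressed) file contents."""
    if is_gzip(path):
        return gzip.open(path, "rb")
    return open(path, "rb")


def detect_format(path) -> str:
    with _open_text_stream(path) as fh:
        for raw in fh:
            if not raw.strip():
                continue
            if raw.startswith(b">"):
                return "fasta"
            if raw.startswith(b"@"):
                return "fastq"
            raise SequenceParseError("file starts with neither '>' nor '@'", 0)
    return "fasta"  # empty file: treated as an empty FASTA


def _scan_fasta(fh) -> Iterator[SequenceRecord]:
    pos = 0
    ordinal = 0
    header_off = None
    name = None
    seq_start = 0
    seq_end = 0
    base_count = 0
    wrap = 0

    def emit():
        nonlocal ordinal
        if base_count == 0:
            raise SequenceParseError(f"record {name!r}: header without sequence", header_off)
        rec = SequenceRecord(ordinal, name, seq_start, seq_end - seq_start, base_count, wrap)
        ordinal += 1
        return rec

    for raw in fh:
        if raw.startswith(b">"):
            if name is not None:
                yield emit()
            header_off = pos
            token = raw[1:].split()
            if not token:
                raise SequenceParseError("empty FASTA header", pos)
            name = token[0].decode("ascii")
            pos += len(raw)
            seq_start = seq_end = pos
            base_count = 0
            wrap = 0
        else:
            if name is None:
                if raw.strip():
                    raise SequenceParseError("sequence data before any header", pos)
                pos += len(raw)
                seq_start = seq_end = pos
                continue
            stripped = raw.rstrip(b"\r\n")
            pos += len(raw)
            if stripped:
                if wrap == 0:
                    wrap = len(stripped)
                base_count += len(stripped)
                seq_end = pos
    if name is not None:
        yield emit()


def _scan_fastq(fh) -> Iterator[SequenceRecord]:
    pos = 0
    ordinal = 0
    while True:
        header = fh.readline()
        if not header:
            return
        if not header.strip():  # tolerate trailing blank lines
            pos += len(header)
            continue
        if not header.startswith(b"@"):
            raise SequenceParseError("FASTQ header does not start with '@'", pos)
        block_off = pos
        token = header[1:].split()
        if not token:
            raise SequenceParseError("empty FASTQ header", pos)
        name = token[0].decode("ascii")
        pos += len(header)
        seq_line = fh.readline()
        seq_off = pos
        plus = None
        qual = None
        if seq_line:
            pos += len(seq_line)
            plus = fh.readline()
            if plus:
                pos += len(plus)
                qual = fh.readline()
                if qual:
                    pos += len(qual)
        if not seq_line or not plus or not qual:
            raise SequenceParseError("truncated FASTQ record (fewer than 4 lines)", block_off)
        if not plus.startswith(b"+"):
            raise SequenceParseError("FASTQ separator line does not start with '+'", block_off)
        seq = seq_line.rstrip(b"\r\n")
        yield SequenceRecord(ordinal, name, seq_off, len(seq_line), len(seq), len(seq))
        ordinal += 1


def scan_records(path, format: Optional[str] = None) -> Iterator[SequenceRecord]:
    """Stream the random-access metadata of every record, in file order."""
    fmt = format or detect_format(path)
    with _open_text_stream(path) as fh:
        scanner = _scan_fasta(fh) if fmt == "fasta" else _scan_fastq(fh)
        yield from scanner


def parse_sequences(path, format: Optional[str] = None) -> Iterator[Tuple[str, str]]:
    """Yield ``(name, sequence)`` pairs in file order.

    Sequences are uppercased with wrapped lines concatenated; FASTQ quality
    lines are ignored.  Names are truncated at the first whitespace.
    """
    fmt = format or detect_format(path)
    with _open_text_stream(path) as fh:
        if fmt == "fasta":
            name = None
            chunks: List[bytes] = []
            pos = 0
            header_off = 0
            for raw in fh:
                if raw.startswith(b">"):
                    if name is not None:
                        if not chunks:
                            raise SequenceParseError(
                                f"record {name!r}: header without sequence", header_off
                            )
                        yield name, b"".join(chunks).decode("ascii").upper()
                    header_off = pos
                    token = raw[1:].split()
                    if not token:
                        raise SequenceParseError("empty FASTA header", pos)
                    name = token[0].decode("ascii")
                    chunks = []
                elif raw.strip():
                    if name is None:
                        raise SequenceParseError("sequence data before any header", pos)
                    chunks.append(raw.rstrip(b"\r\n"))
                pos += len(raw)
            if name is not None:
                if not chunks:
                    raise SequenceParseError(
                        f"record {name!r}: header without sequence", header_off
                    )
                yield name, b"".join(chunks).decode("ascii").upper()
        else:
            for rec_name, seq in _iter_fastq_sequences(fh):
                yield rec_name, seq


def _iter_fastq_sequences(fh) -> Iterator[Tuple[str, str]]:
    pos = 0
    while True:
        header = fh.readline()
        if not header:
            return
        if not header.strip():
            pos += len(header)
            continue
        block_off = pos
        if not header.startswith(b"@"):
            raise SequenceParseError("FASTQ header does not start with '@'", pos)
        name = header[1:].split()[0].decode("ascii")
        pos += len(header)
        seq_line = fh.readline()
        plus = fh.readline() if seq_line else b""
        qual = fh.readline() if plus else b""
        for part in (seq_line, plus, qual):
            pos += len(part)
        if not seq_line or not plus or not qual:
            raise SequenceParseError("truncated FASTQ record (fewer than 4 lines)", block_off)
        yield name, seq_line.rstrip(b"\r\n").decode("ascii").upper()


def _serialize_record(rec: SequenceRecord) -> bytes:
    row = [rec.ordinal, rec.name, rec.offset, rec.byte_length, rec.base_count,
           rec.bases_per_line]
    return zlib.compress(json.dumps(row, separators=(",", ":")).encode("ascii"), 6)


def _deserialize_record(blob: bytes) -> SequenceRecord:
    row = json.loads(zlib.decompress(blob).decode("ascii"))
    return SequenceRecord(*row)


class FAQIndexStore:
    """On-disk random-access index over a FASTA/FASTQ file.

    Lives in a directory holding an SQLite database of compressed rows plus a
    JSON metadata file; supports concurrent readers.
    """

    def __init__(self, path):
        self.path = Path(path)
        meta_path = self.path / _META_NAME
        if not meta_path.exists():
            raise StoreCorruptionError(f"no FAQIndex metadata at {meta_path}")
        with open(meta_path) as fh:
            self.metadata = json.load(fh)
        self.source_path = self.metadata["source_path"]
        self.source_format = self.metadata["source_format"]
        self.record_count = self.metadata["record_count"]
        self._conn = sqlite3.connect(
            f"file:{self.path / _DB_NAME}?mode=ro", uri=True, check_same_thread=False
        )

    def __len__(self) -> int:
        return self.record_count

    def close(self):
        self._conn.close()

    def get_record(self, ordinal: int) -> SequenceRecord:
        if not 0 <= ordinal < self.record_count:
            raise IndexError(f"ordinal {ordinal} out of range [0, {self.record_count})")
        row = self._conn.execute(
            "SELECT data FROM records WHERE ordinal = ?", (ordinal,)
        ).fetchone()
        if row is None:
            raise StoreCorruptionError(f"missing row for ordinal {ordinal}")
        return _deserialize_record(row[0])

    def fetch_sequence(self, ordinal: int) -> Tuple[str, str]:
        """Return ``(name, sequence)`` exactly as the parser would yield it."""
        rec = self.get_record(ordinal)
        with _open_text_stream(self.source_path) as fh:
            fh.seek(rec.offset)
            raw = fh.read(rec.byte_length)
        seq = raw.replace(b"\n", b"").replace(b"\r", b"").decode("ascii").upper()
        if len(seq) != rec.base_count:
            raise StoreCorruptionError(
                f"record {ordinal}: fetched {len(seq)} bases, expected {rec.base_count}"
            )
        return rec.name, seq


def build_faqindex(path, out) -> FAQIndexStore:
    """Index a FASTA/FASTQ file (plain or gzip) for random access by ordinal."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    fmt = detect_format(path)
    db_path = out / _DB_NAME
    if db_path.exists():
        db_path.unlink()
    conn = sqlite3.connect(db_path)
    conn.execute("CREATE TABLE records (ordinal INTEGER PRIMARY KEY, data BLOB NOT NULL)")
    count = 0
    with conn:
        for rec in scan_records(path, fmt):
            conn.execute(
                "INSERT INTO records (ordinal, data) VALUES (?, ?)",
                (rec.ordinal, _serialize_record(rec)),
            )
            count += 1
    conn.close()
    metadata = {
        "format_version": _FORMAT_VERSION,
        "source_path": str(Path(path).resolve()),
        "source_format": fmt,
        "codec": "zlib",
        "compressed_rows": True,
        "record_count": count,
    }
    with open(out / _META_NAME, "w") as fh:
        json.dump(metadata, fh, indent=1)
    logger.info("FAQIndex built: %d records from %s", count, path)
    return FAQIndexStore(out)


def fetch_record(store: FAQIndexStore, ordinal: int) -> Tuple[str, str]:
    """Random access: ``(name, sequence)`` of the record at ``ordinal``."""
    return store.fetch_sequence(ordinal)


def generate_fixture(
    n_seqs: int,
    length_range: Tuple[int, int],
    alphabet: str,
    seed: int,
    out,
    format: str = "fasta",
    line_width: int = 60,
    gzip_output: bool = False,
) -> str:
    """Write a deterministic synthetic FASTA/FASTQ file.

    Residues are drawn i.i.d. uniform from the 4-letter nucleotide or
    20-letter amino-acid alphabet; headers are ``seq_<ordinal>``.  The same
    seed always produces byte-identical output (gzip streams are written
    with a zeroed timestamp).
    """
    lo, hi = length_range
    if n_seqs < 0 or lo < 1 or hi < lo:
        raise ValueError("need n_seqs >= 0 and 1 <= min <= max length")
    letters = NT_LETTERS if alphabet == "nucleotide" else AA_LETTERS
    rng = np.random.default_rng(seed)
    buf = io.BytesIO()
    for i in range(n_seqs):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[j] for j in rng.integers(0, len(letters), size=length))
        if format == "fasta":
            buf.write(f">seq_{i}\n".encode())
            for start in range(0, length, line_width):
                buf.write(seq[start : start + line_width].encode() + b"\n")
        elif format == "fastq":
            buf.write(f"@seq_{i}\n{seq}\n+\n{'I' * length}\n".encode())
        else:
            raise ValueError(f"unknown format {format!r}")
    payload = buf.getvalue()
    out = str(out)
    if gzip_output or out.endswith(".gz"):
        with open(out, "wb") as fh:
            with gzip.GzipFile(filename="", mode="wb", fileobj=fh, mtime=0) as gz:
                gz.write(payload)
    else:
        with open(out, "wb") as fh:
            fh.write(payload)
    return out
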