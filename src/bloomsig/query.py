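"""Exact and thresholded approximate search against a bit-sliced index.

A query sequence is decomposed into its distinct valid k-mers; for each
k-mer the ``h`` bit-slices at its hash positions are retrieved and AND-ed,
giving the samples in which that k-mer is (apparently) present.  A sample is
reported when at least ``T`` percent of the query's counted k-mers are found
(``T = 100`` is exact search).  Because Bloom filters have zero false
negatives, a truly contained query is never missed at any ``T``.

Nucleotide queries against an amino-acid index are translated in all six
reading frames and each frame is scored independently.  Windows containing a
stop codon (``*``) stay in the denominator but can never be found — in a
spurious (non-coding) frame a stop occurs about every 21 codons, so runs of
matchable k-mers are short and such frames cannot reach a high threshold.
Windows containing ``X`` (from ambiguous nucleotides) are excluded from the
denominator by default.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np

from .errors import CompatibilityError
from .index import IndexStore, SlabCache
from .kmers import (
    AMINO_ACID_ALPHABET,
    KmerScheme,
    extract_kmers,
    hash_positions,
    six_frame_translate,
)
from .sequence_io import build_faqindex, parse_sequences

logger = logging.getLogger(__name__)

_NT_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class SearchOptions:
    """Search behaviour.

    ``T`` is the reporting threshold in percent (0 < T <= 100; 100 means
    every counted k-mer must be found).  ``mode`` selects the alphabet
    pairing; ``auto`` infers it from the query and index alphabets.  With
    ``strict_denominator`` every length-k window counts in the denominator,
    including windows invalidated by out-of-alphabet characters.
    """

    T: float = 100.0
    mode: str = "auto"  # auto | nt_on_nt | aa_on_aa | nt_on_aa
    workers: int = 1
    strict_denominator: bool = False

    def __post_init__(self):
        if not 0 < self.T <= 100:
            raise ValueError(f"threshold T must be in (0, 100], got {self.T}")
        if self.mode not in ("auto", "nt_on_nt", "aa_on_aa", "nt_on_aa"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class QueryResult:
    """One reported (query, frame, sample) row.

    ``frame`` is 0 for untranslated queries, 1-6 for six-frame translated
    ones; ``score`` is the percentage of the frame's counted k-mers found
    in the sample.
    """

    query_id: str
    frame: int
    sample: str
    score: float


def score_samples(
    index: IndexStore,
    kmers: Iterable[str],
    cache: SlabCache | None = None,
) -> np.ndarray:
    """Per-sample count of distinct query k-mers present in each sample.

    A k-mer counts as present in sample ``j`` when all ``h`` of its
    bit-slices have bit ``j`` set.  Duplicate k-mers are deduplicated.
    """
    counts = np.zeros(index.Y, dtype=np.int64)
    if cache is None:
        cache = SlabCache()
    for kmer in dict.fromkeys(kmers):
        found = None
        for p in hash_positions(kmer, index.params):
            packed = index.packed_row(p, cache)
            found = packed.copy() if found is None else (found & packed)
        if found is not None:
            counts += np.unpackbits(found, bitorder="little", count=index.Y)
    return counts


def _looks_nucleotide(seq: str) -> bool:
    s = set(seq.upper())
    return bool(s) and s <= _NT_CHARS


def _resolve_mode(index: IndexStore, seq: str, mode: str) -> str:
    idx_alpha = index.params.scheme.alphabet
    if mode != "auto":
        want_idx = "amino_acid" if mode in ("aa_on_aa", "nt_on_aa") else "nucleotide"
        if idx_alpha != want_idx:
            raise CompatibilityError(
                f"mode {mode!r} requires a {want_idx} index, got {idx_alpha}"
            )
        return mode
    if idx_alpha == "nucleotide":
        if not _looks_nucleotide(seq):
            raise CompatibilityError(
                "amino-acid query cannot be searched against a nucleotide index"
            )
        return "nt_on_nt"
    return "nt_on_aa" if _looks_nucleotide(seq) else "aa_on_aa"


def _score_frame(
    index: IndexStore,
    windows: Sequence[str],
    strict: bool,
    translated: bool,
    cache: SlabCache,
) -> Tuple[np.ndarray, int]:
    """Found-count vector and denominator for one (possibly translated) frame.

    Valid windows are looked up; ``*``-containing windows (translated mode)
    count in the denominator but are guaranteed absent; other invalid
    windows are excluded unless ``strict``.
    """
    letters = index.params.scheme.letters
    distinct = dict.fromkeys(windows)
    lookup: List[str] = []
    denom = 0
    for w in distinct:
        if set(w) <= letters:
            lookup.append(w)
            denom += 1
        elif translated and "*" in w and set(w) <= (letters | {"*"}):
            denom += 1  # stop-codon window: counted, never found
        elif strict:
            denom += 1
    counts = score_samples(index, lookup, cache)
    return counts, denom


def _canonical_windows(seq: str, scheme: KmerScheme) -> List[str]:
    """Raw windows for denominator accounting; valid ones per the scheme."""
    k = scheme.k
    s = seq.upper()
    return [s[i : i + k] for i in range(len(s) - k + 1)]


def _emit(query_id, frame, index, counts, denom, T) -> List[QueryResult]:
    if denom == 0:
        return []
    scores = 100.0 * counts / denom
    out = []
    for j in np.nonzero(scores >= T)[0]:
        out.append(QueryResult(query_id, frame, index.sample_names[int(j)], float(scores[j])))
    return out


def _search_one(
    index: IndexStore, query_id: str, seq: str, opts: SearchOptions, cache: SlabCache
) -> List[QueryResult]:
    mode = _resolve_mode(index, seq, opts.mode)
    scheme = index.params.scheme
    if mode in ("nt_on_nt", "aa_on_aa"):
        if len(seq) < scheme.k:
            logger.warning("query %r shorter than k=%d; no rows emitted", query_id, scheme.k)
            return []
        if opts.strict_denominator:
            windows = _canonical_windows(seq, scheme)
            valid = dict.fromkeys(extract_kmers(seq, scheme))
            denom = len(dict.fromkeys(windows))
            counts = score_samples(index, valid, cache)
        else:
            valid = dict.fromkeys(extract_kmers(seq, scheme))
            denom = len(valid)
            counts = score_samples(index, valid, cache)
        if denom == 0:
            logger.warning("query %r has zero counted k-mers; no rows emitted", query_id)
            return []
        return _emit(query_id, 0, index, counts, denom, opts.T)
    # nt_on_aa: score each of the six translated frames independently
    results: List[QueryResult] = []
    frames = six_frame_translate(seq)
    any_counted = False
    for f, aa in enumerate(frames, start=1):
        if len(aa) < scheme.k:
            continue
        windows = _canonical_windows(aa, scheme)
        counts, denom = _score_frame(
            index, windows, opts.strict_denominator, translated=True, cache=cache
        )
        if denom == 0:
            continue
        any_counted = True
        results.extend(_emit(query_id, f, index, counts, denom, opts.T))
    if not any_counted:
        logger.warning(
            "query %r: no frame has counted k-mers (too short after translation?)",
            query_id,
        )
    return results


def search(
    index: IndexStore,
    queries: Union[str, Path],
    opts: SearchOptions = SearchOptions(),
) -> List[QueryResult]:
    """Search raw sequence text or a FASTA/FASTQ file against an index.

    A string that names an existing file is treated as a file of queries
    (a throwaway FAQIndex is built to distribute records across workers);
    anything else is treated as one raw query sequence.
    """
    cache = SlabCache()
    path = Path(str(queries))
    try:
        is_file = path.is_file()
    except OSError:  # e.g. a raw sequence longer than the filename limit
        is_file = False
    if is_file:
        with tempfile.TemporaryDirectory(prefix="faq_query_") as tmp:
            store = build_faqindex(path, tmp)
            pairs = [store.fetch_sequence(i) for i in range(len(store))]
            store.close()
    else:
        pairs = [("query_1", str(queries).strip().upper())]
    results: List[QueryResult] = []
    if opts.workers > 1 and len(pairs) > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=opts.workers) as pool:
            chunks = pool.map(
                lambda p: _search_one(index, p[0], p[1], opts, SlabCache()), pairs
            )
            for chunk in chunks:
                results.extend(chunk)
    else:
        for name, seq in pairs:
            results.extend(_search_one(index, name, seq, opts, cache))
    return results


def search_translated(
    index: IndexStore,
    nt_queries: Union[str, Path],
    opts: SearchOptions = SearchOptions(),
) -> List[QueryResult]:
    """Six-frame translated search of nucleotide queries against an
    amino-acid index; results carry frames 1-6."""
    if index.params.scheme.alphabet != "amino_acid":
        raise CompatibilityError("translated search requires an amino-acid index")
    forced = SearchOptions(
        T=opts.T, mode="nt_on_aa", workers=opts.workers,
        strict_denominator=opts.strict_denominator,
    )
    return search(index, nt_queries, forced)


def sort_results(results: Iterable[QueryResult]) -> List[QueryResult]:
    return sorted(results, key=lambda r: (r.query_id, r.frame, -r.score, r.sample))


def write_results(results: Iterable[QueryResult], out) -> Path:
    """Write results as a TSV with a fixed header and deterministic order."""
    out = Path(out)
    with open(out, "w") as fh:
        fh.write("query_id\tframe\tsample\tscore_percent\n")
        for r in sort_results(results):
            fh.write(f"{r.query_id}\t{r.frame}\t{r.sample}\t{r.score:.2f}\n")
    return out


def read_results(path) -> List[QueryResult]:
    """Parse a results TSV back into QueryResult rows."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            qid, frame, sample, score = line.rstrip("\n").split("\t")
            rows.append(QueryResult(qid, int(frame), sample, float(score)))
    return rows
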