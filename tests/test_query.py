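"""Exact, thresholded, and six-frame translated search."""

import numpy as np
import pytest

from bloomsig import (
    BloomParams,
    KmerScheme,
    SearchOptions,
    build_index,
    build_matrix,
    extract_kmers,
    score_samples,
    search,
    search_translated,
    write_results,
)
from bloomsig.kmers import GENETIC_CODE, reverse_complement
from bloomsig.query import QueryResult, read_results, sort_results
from bloomsig.stats import FprInputs, bloom_fpr

from conftest import AA, build_sample_set, random_kmer_set, random_seq

AA_SCHEME = KmerScheme(k=11, alphabet="amino_acid")

# one representative codon per amino acid, for back-translating proteins
_CODON_OF = {}
for codon, aa in GENETIC_CODE.items():
    _CODON_OF.setdefault(aa, codon)


def encode_protein(protein: str) -> str:
    return "".join(_CODON_OF[a] for a in protein)


def test_indexed_sequence_scores_full_count(small_protein_index):
    idx = small_protein_index["index"]
    for j, (name, seq) in enumerate(small_protein_index["seqs"][:3]):
        kmers = list(dict.fromkeys(extract_kmers(seq, AA_SCHEME)))
        counts = score_samples(idx, kmers)
        assert counts[j] == len(kmers)  # zero false negatives


def test_empty_kmer_list_scores_zero(small_protein_index):
    idx = small_protein_index["index"]
    assert not score_samples(idx, []).any()


def test_duplicates_deduplicated_before_scoring(small_protein_index):
    idx = small_protein_index["index"]
    kmers = ["MKLVNQWERTY"] * 5
    counts = score_samples(idx, kmers)
    assert counts.max() <= 1


def test_found_counts_match_set_oracle_with_fpr_bound(tmp_path):
    """Counts equal the exact k-mer-set oracle plus a nonnegative
    false-positive excess bounded by 5x the analytic rate."""
    rng = np.random.default_rng(43)
    params = BloomParams(m=100_000, h=2, scheme=AA_SCHEME)
    samples = [(f"s{j}", random_kmer_set(rng, 2000, 11)) for j in range(4)]
    sets = {j: set(k) for j, (_, k) in enumerate(samples)}
    mat = build_matrix(samples, params, tmp_path / "m", mem_limit=1 << 20)
    idx = build_index(mat, tmp_path / "i")

    probes = random_kmer_set(rng, 5000, 11)
    counts = score_samples(idx, probes)
    fpr = bloom_fpr(FprInputs(m=params.m, h=params.h, n=2000))
    for j in range(4):
        true = sum(1 for w in probes if w in sets[j])
        excess = counts[j] - true
        assert excess >= 0
        assert excess / len(probes) <= 5 * fpr + 1e-12


def test_own_sample_reported_at_exact_threshold(small_protein_index):
    idx = small_protein_index["index"]
    for j, (name, seq) in enumerate(small_protein_index["seqs"]):
        res = search(idx, seq, SearchOptions(T=100))
        assert any(r.sample == name and r.score == 100.0 for r in res)


def test_threshold_arithmetic_15_of_20(tmp_path):
    rng = np.random.default_rng(47)
    kmers = random_kmer_set(rng, 20, 11)
    params = BloomParams(m=100_000, h=2, scheme=AA_SCHEME)
    mat = build_matrix([("partial", kmers[:15])], params, tmp_path / "m",
                       mem_limit=1 << 20)
    idx = build_index(mat, tmp_path / "i")
    counts = score_samples(idx, kmers)
    assert counts[0] == 15  # no false positives at this tiny load
    hits75 = {r.sample for r in _search_kmers(idx, kmers, 75)}
    hits100 = {r.sample for r in _search_kmers(idx, kmers, 100)}
    assert hits75 == {"partial"} and hits100 == set()


def _search_kmers(idx, kmers, T):
    """Score a bag of k-mers directly, mirroring search()'s emit rule."""
    counts = score_samples(idx, kmers)
    denom = len(dict.fromkeys(kmers))
    out = []
    for j, c in enumerate(counts):
        score = 100.0 * c / denom
        if score >= T:
            out.append(QueryResult("q", 0, idx.sample_names[j], score))
    return out


def test_monotone_in_threshold_and_superset_of_oracle(tmp_path):
    rng = np.random.default_rng(53)
    params = BloomParams(m=50_000, h=2, scheme=AA_SCHEME)
    seqs, samples = build_sample_set(rng, 6, 140, AA_SCHEME)
    sets = {n: set(k) for (n, k), _ in zip(samples, range(6))}
    mat = build_matrix(samples, params, tmp_path / "m", mem_limit=1 << 20)
    idx = build_index(mat, tmp_path / "i")

    for _ in range(100):
        src = seqs[int(rng.integers(0, 6))][1]
        start = int(rng.integers(0, len(src) - 30))
        q = src[start : start + 30]
        qk = set(extract_kmers(q, AA_SCHEME))
        hits100 = {r.sample for r in search(idx, q, SearchOptions(T=100))}
        hits60 = {r.sample for r in search(idx, q, SearchOptions(T=60))}
        assert hits100 <= hits60  # monotone in T
        truly_containing = {n for n, s in sets.items() if qk <= s}
        assert truly_containing <= hits100  # never miss a true containment


def test_query_shorter_than_k_emits_nothing(small_protein_index, caplog):
    idx = small_protein_index["index"]
    with caplog.at_level("WARNING"):
        assert search(idx, "MKV", SearchOptions(T=50)) == []
    assert "shorter than k" in caplog.text


def test_file_queries_match_raw_queries(tmp_path, small_protein_index):
    idx = small_protein_index["index"]
    seqs = small_protein_index["seqs"][:3]
    qf = tmp_path / "q.fa"
    qf.write_text("".join(f">{n}\n{s}\n" for n, s in seqs))
    file_res = sort_results(search(idx, qf, SearchOptions(T=100)))
    raw = []
    for n, s in seqs:
        for r in search(idx, s, SearchOptions(T=100)):
            raw.append(QueryResult(n, r.frame, r.sample, r.score))
    assert file_res == sort_results(raw)
    parallel = sort_results(search(idx, qf, SearchOptions(T=100, workers=3)))
    assert parallel == file_res


def test_translated_query_hits_frame_one(small_protein_index):
    idx = small_protein_index["index"]
    name, protein = small_protein_index["seqs"][2]
    dna = encode_protein(protein)
    res = search_translated(idx, dna, SearchOptions(T=100))
    assert any(r.sample == name and r.frame == 1 and r.score == 100.0 for r in res)


def test_reverse_complement_moves_hit_to_reverse_frames(small_protein_index):
    idx = small_protein_index["index"]
    name, protein = small_protein_index["seqs"][2]
    dna = reverse_complement(encode_protein(protein))
    res = search_translated(idx, dna, SearchOptions(T=100))
    frames = {r.frame for r in res if r.sample == name and r.score == 100.0}
    assert frames and frames <= {4, 5, 6}


def test_noncoding_dna_suppressed_by_stop_codons(small_protein_index):
    """Random DNA cannot reach T=75 against a protein index: stop codons
    break every spurious frame into short matchable runs."""
    idx = small_protein_index["index"]
    rng = np.random.default_rng(59)
    for _ in range(20):
        dna = random_seq(rng, 300, "ACGT")
        assert search_translated(idx, dna, SearchOptions(T=75)) == []


def test_stop_windows_count_in_denominator(small_protein_index):
    idx = small_protein_index["index"]
    name, protein = small_protein_index["seqs"][0]
    # insert an in-frame stop in the middle of the coding sequence
    broken = protein[:40] + "*" + protein[40:]
    dna = encode_protein(broken)
    res = search_translated(idx, dna, SearchOptions(T=100))
    assert not any(r.sample == name and r.frame == 1 for r in res)
    res80 = search_translated(idx, dna, SearchOptions(T=80))
    assert any(r.sample == name and r.frame == 1 for r in res80)


def test_mode_mismatch_raises(small_protein_index):
    from bloomsig.errors import CompatibilityError

    idx = small_protein_index["index"]
    with pytest.raises(CompatibilityError):
        search(idx, "MKLVNQWERTYA", SearchOptions(mode="nt_on_nt"))


def test_write_results_roundtrip_and_ordering(tmp_path):
    rows = [
        QueryResult("q2", 0, "s1", 50.0),
        QueryResult("q1", 2, "s2", 99.5),
        QueryResult("q1", 2, "s1", 99.5),
        QueryResult("q1", 1, "s9", 12.34),
    ]
    out = write_results(rows, tmp_path / "r.tsv")
    text = out.read_text().splitlines()
    assert text[0] == "query_id\tframe\tsample\tscore_percent"
    assert [l.split("\t")[0:2] for l in text[1:]] == [
        ["q1", "1"], ["q1", "2"], ["q1", "2"], ["q2", "0"]]
    # equal scores tie-break by sample name
    assert text[2].split("\t")[2] == "s1"
    assert read_results(out) == sort_results(rows)
    # empty results -> header-only file
    empty = write_results([], tmp_path / "e.tsv")
    assert empty.read_text() == "query_id\tframe\tsample\tscore_percent\n"


def test_search_options_validation():
    with pytest.raises(ValueError):
        SearchOptions(T=0)
    with pytest.raises(ValueError):
        SearchOptions(T=101)
    with pytest.raises(ValueError):
        SearchOptions(mode="bogus")
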