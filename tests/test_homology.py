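import random

import pytest

from mirminer.homology import MatureHit, SearchParams, find_hits, search_all, seed_index
from mirminer.seqio import SequenceRecord, reverse_complement

from _oracles import brute_force_hits, random_rna

MIR156A = "UGACAGAAGAUAGAGAGCAC"  # a real 20-nt mature


def _embed(mature, rng, total=300, at=100):
    bg = random_rna(rng, total)
    return bg[:at] + mature + bg[at + len(mature):]


def test_seed_index_enumerates_words_and_strands():
    idx = seed_index([SequenceRecord("s", "ACGUACGU")], word_size=7,
                     both_strands=False)
    assert idx.words["ACGUACG"] == [("s", "+", 0)]
    assert idx.words["CGUACGU"] == [("s", "+", 1)]
    assert len(idx.words) == 2
    idx3 = seed_index([SequenceRecord("s", "AAAA")], word_size=4,
                      both_strands=False)
    assert idx3.words["AAAA"] == [("s", "+", 0)]
    # reverse strand of poly-A holds poly-U words
    idx7 = seed_index([SequenceRecord("s", "AAAAAAA")], word_size=7)
    assert ("s", "-", 0) in idx7.words["UUUUUUU"]


def test_exact_embedding_found_with_zero_mismatches(rng):
    subject = SequenceRecord("est1", _embed(MIR156A, rng))
    query = SequenceRecord("mir156", MIR156A)
    hits = find_hits(query, seed_index([subject], 7), SearchParams())
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1
    h = plus[0]
    assert (h.subject_start, h.subject_end) == (101, 120)
    assert h.mismatch_count == 0 and h.matched_length == 20
    assert h.aligned_subject == MIR156A


def test_four_substitutions_is_rejected(rng):
    mutated = list(MIR156A)
    for p in (2, 7, 12, 17):
        mutated[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[p]]
    subject = SequenceRecord("est1", _embed("".join(mutated), rng))
    hits = find_hits(SequenceRecord("mir156", MIR156A), seed_index([subject], 7))
    assert all(h.mismatch_count <= 3 for h in hits)
    assert not any(h.subject_start <= 110 <= h.subject_end and h.matched_length == 20
                   and h.mismatch_count == 4 for h in hits)


def test_query_shorter_than_min_match_length_errors():
    idx = seed_index([SequenceRecord("s", "ACGU" * 20)], 7)
    with pytest.raises(ValueError, match="min_match_length"):
        find_hits(SequenceRecord("q", "ACGUACGUACG"), idx)


def test_hit_invariants_enforced():
    with pytest.raises(ValueError, match="mismatch_count"):
        MatureHit("q", "s", 1, 4, "+", 2, "ACGU", "ACGU")
    with pytest.raises(ValueError, match="equal-length"):
        MatureHit("q", "s", 1, 4, "+", 0, "ACGU", "ACG")


def test_agrees_with_brute_force_oracle(rng):
    """Seeded scan equals all-offsets enumeration on random query/subject pairs."""
    params = SearchParams()
    for trial in range(40):
        qseq = random_rna(rng, 21)
        sseq = random_rna(rng, 200)
        if trial % 3 == 0:  # guarantee some signal
            pos = rng.randrange(0, 180)
            sseq = sseq[:pos] + qseq + sseq[pos + 21:]
        subject = SequenceRecord("s", sseq)
        hits = find_hits(SequenceRecord("q", qseq), seed_index([subject], 7), params)
        expected = set()
        for strand in "+-":
            scan_len = len(sseq)
            for diag, (q0, length, mm) in brute_force_hits(qseq, sseq, strand).items():
                s0 = q0 + diag
                if strand == "+":
                    expected.add(("+", s0 + 1, s0 + length, mm))
                else:
                    expected.add(("-", scan_len - (s0 + length) + 1,
                                  scan_len - s0, mm))
        # collapse duplicates across diagonals exactly as the scanner does
        best = {}
        for strand, a, b, mm in expected:
            key = (strand, a, b)
            best[key] = min(best.get(key, mm), mm)
        assert {(h.strand, h.subject_start, h.subject_end): h.mismatch_count
                for h in hits} == best


def test_strand_symmetry(rng):
    """A minus-strand hit equals a plus-strand hit on the reverse complement."""
    qseq = random_rna(rng, 20)
    sseq = random_rna(rng, 150)
    sseq = sseq[:60] + reverse_complement(qseq) + sseq[80:]
    q = SequenceRecord("q", qseq)
    fwd = find_hits(q, seed_index([SequenceRecord("s", sseq)], 7))
    rev = find_hits(q, seed_index(
        [SequenceRecord("s", reverse_complement(sseq))], 7))
    n = len(sseq)
    minus = {(n - h.subject_end + 1, n - h.subject_start + 1, h.mismatch_count)
             for h in fwd if h.strand == "-"}
    plus_on_rc = {(h.subject_start, h.subject_end, h.mismatch_count)
                  for h in rev if h.strand == "+"}
    assert minus == plus_on_rc and minus


def test_aligned_strings_always_equal_length(rng, known_matures):
    db = [SequenceRecord(f"s{i}", random_rna(rng, 250)) for i in range(5)]
    for h in search_all(known_matures, db):
        assert len(h.aligned_query) == len(h.aligned_subject) == h.matched_length


def test_search_all_rejects_empty_reference():
    with pytest.raises(ValueError, match="no query"):
        search_all([], [SequenceRecord("s", "ACGU" * 30)])
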