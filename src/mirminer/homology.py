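"""Seeded ungapped search for conserved mature miRNAs in EST/GSS sequences.

A deterministic replacement for a permissive BLASTN pass: every subject is
k-mer indexed (word size 7 by default), and each query/subject diagonal that
shares at least one exact word is extended without gaps to the longest
window of at least ``min_match_length`` nt with at most ``max_mismatches``
substitutions.  Exhaustive over diagonals, so it has no seed-and-extend
heuristics to miss a window that contains an exact seed word.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .seqio import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class SearchParams:
    """Mature-homology search thresholds.

    Defaults follow the standard plant-homolog screen: 7-nt words, matches
    of at least 16 nt, fewer than 4 substitutions.
    """

    word_size: int = 7
    max_mismatches: int = 3
    min_match_length: int = 16
    scan_reverse_strand: bool = True

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.min_match_length < self.word_size:
            raise ValueError("min_match_length must be >= word_size")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class MatureHit:
    """An ungapped match of a known mature miRNA inside a subject sequence.

    Coordinates are 1-based inclusive on the subject's forward strand.
    ``aligned_query``/``aligned_subject`` are equal-length (no indels); the
    subject string is in mature-sense (i.e. reverse-complemented for '-').
    """

    query_id: str
    subject_id: str
    subject_start: int
    subject_end: int
    strand: str
    mismatch_count: int
    aligned_query: str
    aligned_subject: str
    query_start: int = 1  # 1-based start of the matched part of the query

    @property
    def matched_length(self) -> int:
        return self.subject_end - self.subject_start + 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("ungapped hit requires equal-length aligned strings")
        ham = sum(a != b for a, b in zip(self.aligned_query, self.aligned_subject))
        if ham != self.mismatch_count:
            raise ValueError("mismatch_count disagrees with aligned strings")


class SeedIndex:
    """Exact k-mer index over subject sequences, optionally both strands."""

    def __init__(self, db: list[SequenceRecord], word_size: int,
                 both_strands: bool = True):
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.word_size = word_size
        self.both_strands = both_strands
        self.subjects: dict[str, SequenceRecord] = {}
        # word -> list of (subject_id, strand, 0-based offset on scan string)
        self.words: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
        for rec in db:
            if rec.seq_id in self.subjects:
                raise ValueError(f"duplicate subject id {rec.seq_id!r}")
            self.subjects[rec.seq_id] = rec
            strands = [("+", rec.residues)]
            if both_strands:
                strands.append(("-", reverse_complement(rec.residues)))
            for strand, seq in strands:
                for off in range(len(seq) - word_size + 1):
                    self.words[seq[off:off + word_size]].append(
                        (rec.seq_id, strand, off))

    def scan_string(self, subject_id: str, strand: str) -> str:
        seq = self.subjects[subject_id].residues
        return seq if strand == "+" else reverse_complement(seq)


def seed_index(db: list[SequenceRecord], word_size: int = 7,
               both_strands: bool = True) -> SeedIndex:
    """Build the exact-word index used to enumerate candidate diagonals."""
    return SeedIndex(db, word_size, both_strands)


def _best_window(qseq: str, sseq: str, diag: int, params: SearchParams
                 ) -> tuple[int, int, int] | None:
    """Best window on one diagonal: (q_start, length, mismatches) or None.

    ``diag`` is subject_offset - query_offset on the scan string.  Longest
    window with <= max_mismatches that contains an exact word_size run of
    matches wins; ties resolve to fewer mismatches, then smaller start.
    """
    m, n, w = len(qseq), len(sseq), params.word_size
    lo = max(0, -diag)              # query positions with a subject partner
    hi = min(m, n - diag)
    if hi - lo < params.min_match_length:
        return None
    match = [qseq[q] == sseq[q + diag] for q in range(lo, hi)]
    L = len(match)
    # exact-seed positions: starts of >=w consecutive matches
    run = 0
    seed_end = [False] * L          # True where a w-run ends at this index
    for idx, ok in enumerate(match):
        run = run + 1 if ok else 0
        if run >= w:
            seed_end[idx] = True
    prefix_mm = [0] * (L + 1)
    prefix_seed = [0] * (L + 1)
    for idx in range(L):
        prefix_mm[idx + 1] = prefix_mm[idx] + (0 if match[idx] else 1)
        prefix_seed[idx + 1] = prefix_seed[idx] + (1 if seed_end[idx] else 0)
    best: tuple[int, int, int] | None = None   # (-length, mismatches, start)
    for start in range(L):
        for end in range(start + params.min_match_length, L + 1):
            mm = prefix_mm[end] - prefix_mm[start]
            if mm > params.max_mismatches:
                continue
            # a full w-run inside [start, end): some run must END in
            # [start + w - 1, end)
            if prefix_seed[end] - prefix_seed[min(end, start + w - 1)] == 0:
                continue
            cand = (-(end - start), mm, start)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    neg_len, mm, start = best
    return lo + start, -neg_len, mm


def find_hits(query: SequenceRecord, index: SeedIndex,
              params: SearchParams | None = None) -> list[MatureHit]:
    """All non-redundant seeded matches of one mature miRNA in the index.

    One best window per (subject, strand, diagonal), deduplicated on
    identical subject coordinates.  Coordinates are reported on the forward
    strand; minus-strand aligned strings are in mature sense.
    """
    params = params or SearchParams()
    if len(query) < params.min_match_length:
        raise ValueError(
            f"query {query.seq_id!r} shorter than min_match_length "
            f"({len(query)} < {params.min_match_length})")
    qseq = query.residues
    w = index.word_size
    diagonals: set[tuple[str, str, int]] = set()
    for qoff in range(len(qseq) - w + 1):
        for subject_id, strand, soff in index.words.get(qseq[qoff:qoff + w], ()):
            if strand == "-" and not params.scan_reverse_strand:
                continue
            diagonals.add((subject_id, strand, soff - qoff))
    hits: dict[tuple[str, str, int, int], MatureHit] = {}
    for subject_id, strand, diag in sorted(diagonals):
        sseq = index.scan_string(subject_id, strand)
        found = _best_window(qseq, sseq, diag, params)
        if found is None:
            continue
        q_start, length, mm = found
        s0 = q_start + diag                     # 0-based on scan string
        n = len(sseq)
        if strand == "+":
            start, end = s0 + 1, s0 + length
        else:                                    # map back to forward strand
            start, end = n - (s0 + length) + 1, n - s0
        key = (subject_id, strand, start, end)
        hit = MatureHit(
            query_id=query.seq_id, subject_id=subject_id,
            subject_start=start, subject_end=end, strand=strand,
            mismatch_count=mm,
            aligned_query=qseq[q_start:q_start + length],
            aligned_subject=sseq[s0:s0 + length],
            query_start=q_start + 1,
        )
        prev = hits.get(key)
        if prev is None or (hit.mismatch_count, hit.query_id) < (
                prev.mismatch_count, prev.query_id):
            hits[key] = hit
    return sorted(hits.values(), key=lambda h: (
        h.subject_id, h.strand, h.subject_start, h.subject_end))


def search_all(queries: list[SequenceRecord], db: list[SequenceRecord],
               params: SearchParams | None = None) -> list[MatureHit]:
    """Run every query against the database; one shared index build."""
    params = params or SearchParams()
    if not queries:
        raise ValueError("no query miRNAs supplied")
    index = seed_index(db, params.word_size, both_strands=params.scan_reverse_strand)
    out: list[MatureHit] = []
    for q in queries:
        out.extend(find_hits(q, index, params))
    return out
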