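"""Precursor window excision around mature hits, and the coding screen.

Windows take up to ``flank`` nt (default 200) on each side of the hit; when
the subject is shorter the whole available sequence is used.  The coding
screen is a local six-frame ORF-length heuristic: a window is dropped when
a long open reading frame overlaps the mature site.  This intentionally
stands in for a remote protein-database search and is documented as such;
it can be disabled outright.
"""

from __future__ import annotations

from dataclasses import dataclass

from .homology import MatureHit
from .seqio import SequenceRecord, reverse_complement

DEFAULT_FLANK = 200
DEFAULT_MIN_ORF_AA = 80

_STOPS = {"UAA", "UAG", "UGA"}


@dataclass(frozen=True)
class PrecursorCandidate:
    """An excised precursor window in mature-sense orientation.

    ``window_start``/``window_end`` are 1-based inclusive on the subject's
    forward strand; ``mature_offset`` is the 1-based position of the
    mature's first nucleotide within ``window_seq``.
    """

    hit: MatureHit
    window_seq: str
    window_start: int
    window_end: int
    mature_offset: int
    truncated: bool

    @property
    def mature_span(self) -> tuple[int, int]:
        """1-based inclusive mature coordinates within the window."""
        return self.mature_offset, self.mature_offset + self.hit.matched_length - 1

    @property
    def provenance(self) -> str:
        h = self.hit
        return (f"{h.subject_id}|{h.strand}|{self.window_start}-{self.window_end}"
                f"|{h.query_id}")


def excise_window(hit: MatureHit, subject: SequenceRecord,
                  flank: int = DEFAULT_FLANK) -> PrecursorCandidate:
    """Cut the candidate precursor window around a hit, clipped to the subject.

    Minus-strand hits are reported reverse-complemented so the mature always
    reads 5'->3' within the window.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    n = len(subject)
    if hit.subject_id != subject.seq_id:
        raise ValueError(f"hit subject {hit.subject_id!r} != record {subject.seq_id!r}")
    if not (1 <= hit.subject_start <= hit.subject_end <= n):
        raise ValueError(f"hit coordinates {hit.subject_start}-{hit.subject_end} "
                         f"outside subject of {n} nt")
    w_start = max(1, hit.subject_start - flank)
    w_end = min(n, hit.subject_end + flank)
    truncated = (w_start > hit.subject_start - flank) or (w_end < hit.subject_end + flank)
    window = subject.residues[w_start - 1:w_end]
    if hit.strand == "+":
        offset = hit.subject_start - w_start + 1
    else:
        window = reverse_complement(window)
        offset = w_end - hit.subject_end + 1
    cand = PrecursorCandidate(hit, window, w_start, w_end, offset, truncated)
    lo, hi = cand.mature_span
    if window[lo - 1:hi] != hit.aligned_subject:
        raise ValueError("excised window does not reproduce the aligned mature")
    return cand


def _orf_spans(seq: str, min_orf_aa: int,
               require_stop: bool = False) -> list[tuple[int, int]]:
    """0-based [start, end) nucleotide spans of ORFs with >= min_orf_aa codons.

    An ORF runs from AUG to the first in-frame stop (stop excluded from the
    codon count).  With ``require_stop`` a reading frame must actually reach
    its stop codon inside the sequence; otherwise an AUG with no downstream
    stop reads through to the end (appropriate for partial cDNAs).
    """
    spans = []
    for frame in range(3):
        codons = [seq[k:k + 3] for k in range(frame, len(seq) - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] != "AUG":
                i += 1
                continue
            j = i
            while j < len(codons) and codons[j] not in _STOPS:
                j += 1
            complete = j < len(codons)
            if j - i >= min_orf_aa and (complete or not require_stop):
                spans.append((frame + 3 * i, frame + 3 * j))
            i = j + 1
    return spans


def six_frame_orfs(seq: str, min_orf_aa: int,
                   require_stop: bool = True) -> list[tuple[int, int]]:
    """Complete ORF spans on both strands, in forward coordinates (0-based)."""
    spans = list(_orf_spans(seq, min_orf_aa, require_stop))
    n = len(seq)
    for a, b in _orf_spans(reverse_complement(seq), min_orf_aa, require_stop):
        spans.append((n - b, n - a))
    return sorted(spans)


def coding_screen(candidate: PrecursorCandidate,
                  min_orf_aa: int = DEFAULT_MIN_ORF_AA) -> str:
    """'drop_coding' if a long ORF in any of six frames overlaps the mature.

    A heuristic protein-coding filter: precursor hairpins sit in noncoding
    sequence, so a >= min_orf_aa-codon reading frame across the mature site
    marks the window as likely mRNA coding sequence.
    """
    m_lo, m_hi = candidate.mature_span      # 1-based inclusive
    for a, b in six_frame_orfs(candidate.window_seq, min_orf_aa):
        if a < m_hi and b > m_lo - 1:       # overlap in 0-based half-open terms
            return "drop_coding"
    return "retain"
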