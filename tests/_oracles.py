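"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and seeded-scan
code paths: structures are enumerated exhaustively and scored by loop
decomposition; homology hits are found by trying every alignment offset and
every window.
"""

from __future__ import annotations

import random

from mirminer.energy import default_model, evaluate_structure
from mirminer.seqio import reverse_complement

_MODEL = default_model()


def all_nested_structures(seq: str) -> list[list[tuple[int, int]]]:
    """Every nested structure over legal pairs with hairpin loops >= 3 nt."""
    n = len(seq)
    pairable = [[_MODEL.pair_type(seq[i], seq[j]) >= 0 and j - i - 1 >= 3
                 for j in range(n)] for i in range(n)]

    def structs(positions: list[int]) -> list[list[tuple[int, int]]]:
        if not positions:
            return [[]]
        i, rest = positions[0], positions[1:]
        out = list(structs(rest))
        for idx, j in enumerate(rest):
            if pairable[i][j]:
                for a in structs(rest[:idx]):
                    for b in structs(rest[idx + 1:]):
                        out.append([(i, j)] + a + b)
        return out

    return structs(list(range(n)))


def brute_force_mfe(seq: str) -> float:
    """Minimum energy over exhaustive enumeration (0.0 = open chain)."""
    best = 0.0
    n = len(seq)
    for pairs in all_nested_structures(seq):
        partner = [-1] * n
        for a, b in pairs:
            partner[a], partner[b] = b, a
        e = evaluate_structure(seq, partner, _MODEL)
        if e < best:
            best = e
    return best


def brute_force_hits(qseq: str, sseq: str, strand: str, word_size: int = 7,
                     max_mismatches: int = 3, min_match_length: int = 16):
    """Best window per diagonal by trying every offset and every window.

    Returns {diagonal: (q_start0, length, mismatches)} using the same
    canonical ordering the scanner promises: longest window first, then
    fewest mismatches, then smallest start.  ``sseq`` is the scan string
    (already reverse-complemented for '-')."""
    scan = sseq if strand == "+" else reverse_complement(sseq)
    m, n = len(qseq), len(scan)
    out = {}
    for diag in range(-m + 1, n):
        best = None
        for q_start in range(m):
            s_start = q_start + diag
            if s_start < 0:
                continue
            for length in range(min_match_length, m - q_start + 1):
                if s_start + length > n:
                    break
                qw = qseq[q_start:q_start + length]
                sw = scan[s_start:s_start + length]
                mm = sum(a != b for a, b in zip(qw, sw))
                if mm > max_mismatches:
                    continue
                # must contain an exact word_size run of matches
                run = best_run = 0
                for a, b in zip(qw, sw):
                    run = run + 1 if a == b else 0
                    best_run = max(best_run, run)
                if best_run < word_size:
                    continue
                cand = (-length, mm, q_start)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out[diag] = (best[2], -best[0], best[1])
    return out


def random_rna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(length))
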