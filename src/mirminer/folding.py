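"""Minimum-free-energy RNA secondary structure prediction and hairpin geometry.

The fold is a nested-structure dynamic program over the nearest-neighbor
model in :mod:`mirminer.energy` (stacking + loop-length penalties, affine
multiloops, hairpin loops of at least 3 nt, no pseudoknots).  It returns a
single deterministic MFE structure; ties during traceback resolve toward
unpaired bases, then toward the leftmost admissible branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import _kernel
from .energy import PAIR_TYPE, EnergyModel, default_model, encode, evaluate_structure

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 1000
_EPS = 1e-7
_MAX_STAR_JUMP = 10   # largest extra partner jump tolerated inside one star block

Arm = str  # {"5p", "3p", "loop"} per position; geometry adds "straddles_loop", "unpaired"


@dataclass(frozen=True)
class SecondaryStructure:
    """A folded sequence: per-position partner map (0-based, -1 = unpaired)."""

    residues: str
    partner: tuple[int, ...]
    mfe_kcal_mol: float

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.partner) if j > i)

    def terminal_loops(self) -> list[tuple[int, int]]:
        """Closing pairs (i, j), 0-based, of hairpin loops (no pairs inside)."""
        loops = []
        for i, j in enumerate(self.partner):
            if j > i and all(self.partner[k] < 0 for k in range(i + 1, j)):
                loops.append((i, j))
        return loops

    def stemloop_span(self, closing: tuple[int, int],
                      max_junction_gap: int | None = None) -> tuple[int, int]:
        """Outermost pair, 0-based, of the helix run enclosing a terminal loop.

        Walks outward through stacks, bulges and internal loops; stops at a
        multiloop or the exterior loop.  With ``max_junction_gap`` set, the
        walk also stops at any bulge/internal loop carrying more than that
        many unpaired nucleotides — junctions looser than that are treated
        as breaks between the stem-loop proper and incidental flanking
        helices.
        """
        parent = self._parent_map()
        a, b = closing
        while True:
            p = parent.get((a, b))
            if p is None:
                return a, b
            pa, pb = p
            inner_pairs = [k for k in range(pa + 1, a) if self.partner[k] >= 0]
            inner_pairs += [k for k in range(b + 1, pb) if self.partner[k] >= 0]
            if inner_pairs:  # (a,b) shares a multiloop with other branches
                return a, b
            gap = (a - pa - 1) + (pb - b - 1)
            if max_junction_gap is not None and gap > max_junction_gap:
                return a, b
            a, b = pa, pb

    def _parent_map(self) -> dict[tuple[int, int], tuple[int, int]]:
        parent: dict[tuple[int, int], tuple[int, int]] = {}
        stack: list[tuple[int, int]] = []
        for i, j in enumerate(self.partner):
            if j > i:
                if stack:
                    parent[(i, j)] = stack[-1]
                stack.append((i, j))
            elif 0 <= j < i:
                stack.pop()
        return parent

    @cached_property
    def hairpin_loop_span(self) -> tuple[int, int] | None:
        """1-based [i, j] of the terminal loop of the longest stem-loop."""
        loops = self.terminal_loops()
        if not loops:
            return None
        best = max(loops, key=lambda c: (self.stemloop_span(c)[1]
                                         - self.stemloop_span(c)[0], -c[0]))
        return best[0] + 2, best[1]

    def arm_of(self, pos_1based: int) -> Arm:
        """Which side of the main terminal loop a position falls on."""
        span = self.hairpin_loop_span
        if span is None:
            return "5p" if pos_1based <= len(self) // 2 else "3p"
        lo, hi = span
        if pos_1based < lo:
            return "5p"
        if pos_1based > hi:
            return "3p"
        return "loop"


def fold_mfe(residues: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Fold a sequence to its minimum-free-energy nested structure.

    Deterministic; the returned energy equals the loop-decomposition energy
    of the returned structure.  Rejects ambiguous characters and sequences
    outside 10..1000 nt.
    """
    model = model or default_model()
    n = len(residues)
    if not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise ValueError(f"sequence length {n} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    seq = encode(residues)
    V, WM, W = _kernel.fold_matrices(
        seq, PAIR_TYPE, model.stack, model.hairpin, model.bulge, model.internal,
        model.ml_closing, model.ml_branch, model.ml_unpaired,
        model.min_hairpin_loop, model.max_internal_span,
    )
    partner = _traceback(seq, V, WM, W, model)
    mfe = float(W[n - 1])
    return SecondaryStructure(residues, tuple(partner), mfe)


def _traceback(seq: np.ndarray, V: np.ndarray, WM: np.ndarray, W: np.ndarray,
               model: EnergyModel) -> list[int]:
    n = seq.shape[0]
    partner = [-1] * n
    min_hp = model.min_hairpin_loop
    max_int = model.max_internal_span

    def close(x: float, y: float) -> bool:
        return abs(x - y) <= _EPS

    def trace_V(i: int, j: int) -> None:
        partner[i], partner[j] = j, i
        target = V[i, j]
        if j - i - 1 >= min_hp and close(target, model.hairpin[j - i - 1]):
            return
        pt = PAIR_TYPE[seq[i], seq[j]]
        for size in range(0, max_int + 1):          # smallest loop first
            for u5 in range(0, size + 1):
                u3 = size - u5
                k, l = i + 1 + u5, j - 1 - u3
                if not (i < k < l < j) or V[k, l] >= _kernel.INF:
                    continue
                if size == 0:
                    pt_in = PAIR_TYPE[seq[k], seq[l]]
                    e = model.stack[pt, pt_in] + V[k, l]
                elif u5 == 0 or u3 == 0:
                    e = model.bulge[size] + V[k, l]
                else:
                    e = model.internal[size] + V[k, l]
                if close(target, e):
                    trace_V(k, l)
                    return
        for k in range(i + 2, j):
            if WM[i + 1, k - 1] < _kernel.INF and WM[k, j - 1] < _kernel.INF:
                e = model.ml_closing + model.ml_branch + WM[i + 1, k - 1] + WM[k, j - 1]
                if close(target, e):
                    trace_WM(i + 1, k - 1)
                    trace_WM(k, j - 1)
                    return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_WM(i: int, j: int) -> None:
        target = WM[i, j]
        if i < j and close(target, WM[i + 1, j] + model.ml_unpaired):
            trace_WM(i + 1, j)
            return
        if i < j and close(target, WM[i, j - 1] + model.ml_unpaired):
            trace_WM(i, j - 1)
            return
        if V[i, j] < _kernel.INF and close(target, V[i, j] + model.ml_branch):
            trace_V(i, j)
            return
        for k in range(i + 1, j + 1):
            if WM[i, k - 1] < _kernel.INF and WM[k, j] < _kernel.INF \
                    and close(target, WM[i, k - 1] + WM[k, j]):
                trace_WM(i, k - 1)
                trace_WM(k, j)
                return
        raise AssertionError("traceback failed in WM")  # pragma: no cover

    j = n - 1
    while j >= 0:
        left = W[j - 1] if j > 0 else 0.0
        if close(W[j], left):        # ties resolve toward fewer pairs
            j -= 1
            continue
        done = False
        for i in range(0, j + 1):
            li = W[i - 1] if i > 0 else 0.0
            if V[i, j] < _kernel.INF and close(W[j], li + V[i, j]):
                trace_V(i, j)
                j = i - 1
                done = True
                break
        if not done:  # pragma: no cover
            raise AssertionError("traceback failed in W")
    return partner


@dataclass(frozen=True)
class HairpinGeometry:
    """Placement of a mature sequence within a folded hairpin."""

    arm: str                       # 5p | 3p | straddles_loop | unpaired
    star_span: tuple[int, int] | None  # 1-based, with 2-nt 3' overhang
    loop_span: tuple[int, int] | None  # 1-based terminal loop used


def hairpin_geometry(structure: SecondaryStructure,
                     mature_span: tuple[int, int]) -> HairpinGeometry:
    """Locate a mature span relative to the terminal loop and derive miRNA*.

    The star span is the range of positions paired to the mature, extended
    by the 2-nt 3' overhang of Dicer products.
    """
    m_lo, m_hi = mature_span
    n = len(structure)
    if not (1 <= m_lo <= m_hi <= n):
        raise ValueError(f"mature span {mature_span} outside sequence of {n} nt")
    paired = [p for p in range(m_lo - 1, m_hi) if structure.partner[p] >= 0]
    if not paired:
        return HairpinGeometry("unpaired", None, None)

    loops = structure.terminal_loops()
    if not loops:
        return HairpinGeometry("unpaired", None, None)

    def mature_pairs_in(closing: tuple[int, int]) -> int:
        sa, sb = structure.stemloop_span(closing)
        return sum(1 for p in paired if sa <= p <= sb)

    a, b = max(loops, key=lambda c: (mature_pairs_in(c), -c[0]))
    loop_lo, loop_hi = a + 1, b - 1           # 0-based loop positions
    loop_span = (loop_lo + 1, loop_hi + 1)

    if m_lo - 1 <= loop_hi and m_hi - 1 >= loop_lo:
        return HairpinGeometry("straddles_loop", None, loop_span)

    # strict majority call: stray terminal base pairs into the flanks must
    # not disqualify an otherwise clean arm placement — the positions they
    # occupy still count against the mature/star duplex downstream
    cons5 = [p for p in paired
             if p < loop_lo and structure.partner[p] > loop_hi]
    cons3 = [p for p in paired
             if p > loop_hi and structure.partner[p] < loop_lo]
    if len(cons5) > len(paired) / 2:
        arm, consistent = "5p", cons5
    elif len(cons3) > len(paired) / 2:
        arm, consistent = "3p", cons3
    else:
        return HairpinGeometry("straddles_loop", None, loop_span)

    # the star is the dominant coherent antiparallel block of partners; a
    # stray mature base pairing elsewhere on the same side must not stretch
    # the span (it counts against the duplex as a mismatch instead)
    blocks: list[list[int]] = [[consistent[0]]]
    for prev, cur in zip(consistent, consistent[1:]):
        jump = abs(structure.partner[prev] - structure.partner[cur])
        if jump > (cur - prev) + _MAX_STAR_JUMP:
            blocks.append([])
        blocks[-1].append(cur)
    core = max(blocks, key=len)
    partners = sorted(structure.partner[p] for p in core)
    star_lo = partners[0] + 1
    star_hi = min(partners[-1] + 2, n - 1) + 1   # 2-nt 3' overhang, clipped
    return HairpinGeometry(arm, (star_lo, star_hi), loop_span)


def write_dotbracket(structure: SecondaryStructure) -> str:
    """Vienna-style two-line text: sequence, dot-bracket with energy."""
    return f"{structure.residues}\n{structure.dotbracket} ({structure.mfe_kcal_mol:.2f})\n"


def parse_dotbracket(residues: str, dotbracket: str,
                     model: EnergyModel | None = None) -> SecondaryStructure:
    """Rebuild a structure from dot-bracket; energy is recomputed from loops."""
    if len(residues) != len(dotbracket):
        raise ValueError("sequence and dot-bracket lengths differ")
    partner = [-1] * len(residues)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at column {i + 1}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    energy = evaluate_structure(residues, partner, model)
    return SecondaryStructure(residues, tuple(partner), energy)
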