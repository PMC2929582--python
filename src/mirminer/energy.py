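"""Nearest-neighbor free-energy model shared by hairpin folding and duplex scoring.

The model is a simplified Turner-style parameterization at 37 C: a 6x6
stacking table over the canonical pairs (A-U, U-A, C-G, G-C, G-U, U-G),
length-indexed initiation penalties for hairpin, bulge and internal loops
with logarithmic extrapolation beyond the tabulated sizes, and an affine
multiloop term.  Parameters live in versioned TSV data files so the model
can be swapped without touching code.  No dangling-end or terminal-pair
corrections are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from math import log

import numpy as np

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
# pair-type lookup: PAIR_TYPE[b1, b2] = index into PAIR_NAMES, or -1
PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _k, _p in enumerate(PAIR_NAMES):
    PAIR_TYPE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _k

MAX_LOOP_TABLE = 1000  # loop arrays are pre-extrapolated to this size


@dataclass(frozen=True)
class EnergyModel:
    """Parameter bundle consumed by the folding kernel and duplex scorer."""

    stack: np.ndarray      # (6, 6) kcal/mol
    hairpin: np.ndarray    # indexed by loop size, inf below min size
    bulge: np.ndarray
    internal: np.ndarray
    ml_closing: float
    ml_branch: float
    ml_unpaired: float
    min_hairpin_loop: int
    max_internal_span: int
    duplex_init: float
    duplex_mismatch_open: float
    duplex_mismatch_nt: float

    def pair_type(self, b1: str, b2: str) -> int:
        i, j = BASE_INDEX.get(b1, -1), BASE_INDEX.get(b2, -1)
        if i < 0 or j < 0:
            return -1
        return int(PAIR_TYPE[i, j])

    def can_pair(self, b1: str, b2: str) -> bool:
        return self.pair_type(b1, b2) >= 0


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("mirminer.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _extrapolated(table: dict[int, float], lxc: float, min_size: int) -> np.ndarray:
    out = np.full(MAX_LOOP_TABLE + 1, np.inf)
    max_tab = max(table)
    for size, val in table.items():
        out[size] = val
    for size in range(min_size, MAX_LOOP_TABLE + 1):
        if not np.isfinite(out[size]):
            out[size] = table[max_tab] + lxc * log(size / max_tab)
    return out


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    """Load the packaged parameter files (cached singleton)."""
    stack_rows = _read_tsv("stack_energies.tsv")
    header = stack_rows[0][1:]
    assert tuple(header) == PAIR_NAMES
    stack = np.zeros((6, 6))
    for row in stack_rows[1:]:
        i = PAIR_NAMES.index(row[0])
        stack[i, :] = [float(x) for x in row[1:]]

    tables: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    scalars: dict[str, float] = {}
    for key, size, value in _read_tsv("loop_params.tsv")[1:]:
        if key in tables:
            tables[key][int(size)] = float(value)
        else:
            scalars[key] = float(value)

    lxc = scalars["lxc"]
    return EnergyModel(
        stack=stack,
        hairpin=_extrapolated(tables["hairpin"], lxc, min(tables["hairpin"])),
        bulge=_extrapolated(tables["bulge"], lxc, 1),
        internal=_extrapolated(tables["internal"], lxc, 2),
        ml_closing=scalars["multiloop_closing"],
        ml_branch=scalars["multiloop_branch"],
        ml_unpaired=scalars["multiloop_unpaired"],
        min_hairpin_loop=int(scalars["min_hairpin_loop"]),
        max_internal_span=int(scalars["max_internal_span"]),
        duplex_init=scalars["duplex_init"],
        duplex_mismatch_open=scalars["duplex_mismatch_open"],
        duplex_mismatch_nt=scalars["duplex_mismatch_nt"],
    )


def encode(residues: str) -> np.ndarray:
    """Map an unambiguous RNA string to integer codes for the kernel."""
    try:
        return np.array([BASE_INDEX[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"ambiguous or illegal residue {exc.args[0]!r}") from None


def evaluate_structure(residues: str, partner: list[int] | np.ndarray,
                       model: EnergyModel | None = None) -> float:
    """Free energy of a given nested structure by loop decomposition.

    Independent of the folding DP: walks the loop tree (hairpins, stacks,
    bulges, internal loops, multiloops) and sums their contributions.
    Exterior-loop bases contribute nothing.  Raises on illegal pairs,
    non-involutive partner maps, or pseudoknots.
    """
    model = model or default_model()
    n = len(residues)
    partner = list(partner)
    pairs = []
    for i, j in enumerate(partner):
        if j < 0:
            continue
        if partner[j] != i or j == i:
            raise ValueError("partner map is not an involution")
        if i < j:
            if model.pair_type(residues[i], residues[j]) < 0:
                raise ValueError(f"illegal pair {residues[i]}{residues[j]} at {i},{j}")
            pairs.append((i, j))
    for (i, j) in pairs:  # nestedness
        for (k, l) in pairs:
            if i < k < j < l:
                raise ValueError("pseudoknotted structure")

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        kids = []
        k = i + 1
        while k < j:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    def loop_energy(i: int, j: int) -> float:
        kids = children_of(i, j)
        unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
        if not kids:
            if unpaired < model.min_hairpin_loop:
                raise ValueError(f"hairpin loop of {unpaired} nt below minimum")
            return float(model.hairpin[unpaired])
        if len(kids) == 1:
            (k, l) = kids[0]
            u5, u3 = k - i - 1, j - l - 1
            if u5 == 0 and u3 == 0:
                pt_out = model.pair_type(residues[i], residues[j])
                pt_in = model.pair_type(residues[k], residues[l])
                return float(model.stack[pt_out, pt_in])
            if u5 == 0 or u3 == 0:
                return float(model.bulge[u5 + u3])
            return float(model.internal[u5 + u3])
        return (model.ml_closing + model.ml_branch * (len(kids) + 1)
                + model.ml_unpaired * unpaired)

    total = 0.0
    for (i, j) in pairs:
        total += loop_energy(i, j)
    return total
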