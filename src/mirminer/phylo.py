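"""Family-level precursor comparison: pairwise identity distances and NJ trees.

Precursors within one miRNA family are compared by Needleman-Wunsch global
alignment (match +1, mismatch -1, gap -2); distance is one minus the
fraction of identical alignment columns.  A neighbor-joining tree is built
on the resulting matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import Align
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .seqio import SequenceRecord


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric (1 - identity) distances over labelled sequences."""

    labels: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distances must be symmetric with a zero diagonal")

    def to_tsv(self) -> str:
        out = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            out.append(lab + "\t" + "\t".join(f"{x:.4f}" for x in self.distances[i]))
        return "\n".join(out) + "\n"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity of the optimal global alignment of two sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(a, b)[0]
    sa, sb = alignment[0], alignment[1]
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa)


def distance_matrix(records: list[SequenceRecord]) -> DistanceMatrix:
    """All-vs-all (1 - identity) distances, in input order."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(records[i].residues, records[j].residues)
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(tuple(r.seq_id for r in records), d)


def neighbor_joining(matrix: DistanceMatrix) -> str:
    """Unrooted NJ tree in newick form; requires at least 3 taxa.

    Uses the standard Q-criterion agglomeration; ties resolve by the input
    label order, so identical matrices give identical newick strings.
    """
    if len(matrix.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    dm = _SkbioDM(matrix.distances, ids=list(matrix.labels))
    tree = _skbio_nj(dm)
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
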