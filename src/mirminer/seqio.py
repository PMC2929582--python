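"""FASTA I/O and basic RNA sequence utilities.

Everything downstream works on a single canonical alphabet: RNA (U, upper
case).  DNA input is converted on read; ambiguity codes (N, IUPAC) are kept
but flagged so folding and duplex stages can refuse them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class SourceTag(str, enum.Enum):
    """Origin of a sequence collection: expressed (EST) or genomic survey (GSS)."""

    EST = "EST"
    GSS = "GSS"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry after normalization to upper-case RNA."""

    seq_id: str
    residues: str
    description: str = ""
    source_tag: SourceTag = SourceTag.UNKNOWN

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.seq_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_ambiguous(self) -> bool:
        """True if the sequence carries any non-ACGU character."""
        return any(c not in RNA_ALPHABET for c in self.residues)

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)


def normalize_rna(raw: str) -> str:
    """Upper-case and convert T to U. Non-ACGU characters pass through."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path, source_tag: SourceTag = SourceTag.UNKNOWN) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, in file order.

    Raises ``ValueError`` on an empty file, a duplicate id, or a record with
    no sequence lines.  Ambiguity characters are retained and noted in the
    record description.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_rna(str(rec.seq))
        if not residues:
            raise ValueError(f"record {rec.id!r} in {path} has no sequence")
        desc = rec.description[len(rec.id):].strip()
        if any(c not in RNA_ALPHABET for c in residues):
            desc = (desc + " [ambiguous]").strip()
        records.append(SequenceRecord(rec.id, residues, desc, source_tag))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-line FASTA wrapped at 60 columns."""
    bio = (
        SeqRecord(Seq(r.residues), id=r.seq_id, description=r.description)
        for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(residues: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C, N->N)."""
    if not residues:
        raise ValueError("cannot reverse-complement an empty sequence")
    bad = set(residues) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal characters for reverse complement: {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


def au_fraction(residues: str) -> float:
    """(A+U) count over total length; ambiguity characters dilute only."""
    if not residues:
        raise ValueError("au_fraction of empty sequence")
    return (residues.count("A") + residues.count("U")) / len(residues)


def gc_fraction(residues: str) -> float:
    """(G+C) count over total length."""
    if not residues:
        raise ValueError("gc_fraction of empty sequence")
    return (residues.count("G") + residues.count("C")) / len(residues)


def iter_windows(residues: str, width: int) -> Iterator[tuple[int, str]]:
    """Yield (0-based start, window) for every window of the given width."""
    for i in range(len(residues) - width + 1):
        yield i, residues[i : i + width]
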